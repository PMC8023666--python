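{
  "config": {
    "seed": 7,
    "budget": 150,
    "e_cut": 2.0,
    "backend": {
      "kind": "analytic",
      "generate": {"dimension": 2, "seed": 7, "minima_range": [4, 8]}
    },
    "search": {"stop_on_convergence": false}
  },
  "counts": {
    "acquisitions": 150,
    "minima_found": 150,
    "minima_after_purge": 7,
    "relaxations": 7
  },
  "true_grid_minima": 7,
  "relaxed_energies": [
    -0.6505179572149827,
    -0.6491652909282075,
    -0.5582189438920742,
    -0.5555239378816859,
    -0.5548978878313212,
    -0.5378884830644514,
    -0.3209403308422986
  ]
}
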