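"""End-to-end orchestration: search -> minima -> purge -> relax -> rank.

The pipeline is driven by a YAML/dict configuration and writes every stage
output (trace CSV, minima CSV/XYZ, hierarchy CSV/JSON) plus a run manifest
into the output directory.  Re-running with the same config and seed
reproduces the manifest counts and the hierarchy table.
"""

from __future__ import annotations

import datetime
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import minimize as _scipy_minimize

from . import __version__, calculators, minima as minima_mod, refine, search
from .errors import ConfigError
from .geometry import MoleculeModel, wrap_angle
from .xyz import read_xyz, write_xyz


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    started: str = ""
    finished: str = ""
    outputs: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    if not os.path.exists(path_or_dict):
        raise ConfigError(f"config file not found: {path_or_dict}")
    with open(path_or_dict) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _build_backend(cfg: dict):
    """Returns (energy_fn, dim, molecule_or_None, cartesian_calculator_or_None,
    true_pes_or_None)."""
    backend = cfg.get("backend", {}) or {}
    kind = backend.get("kind", "analytic")
    molecule = None
    if "molecule" in cfg and cfg["molecule"]:
        mc = cfg["molecule"]
        xyz_path = mc.get("xyz")
        if not xyz_path or not os.path.exists(xyz_path):
            raise ConfigError(f"molecule file not found: {xyz_path}")
        elements, coords, _ = read_xyz(xyz_path)[0]
        dihedrals = mc.get("dihedrals")
        if not dihedrals:
            raise ConfigError("molecule.dihedrals must list atom quadruples")
        molecule = MoleculeModel(elements, coords,
                                 [tuple(q) for q in dihedrals],
                                 bonds=[tuple(b) for b in mc["bonds"]]
                                 if mc.get("bonds") else None)
    if kind == "analytic":
        if backend.get("pes_json"):
            pes = calculators.AnalyticTorsionalPES.from_json(backend["pes_json"])
        elif backend.get("generate"):
            g = backend["generate"]
            pes = calculators.generate_test_pes(
                int(g["dimension"]), int(g.get("seed", cfg.get("seed", 0))),
                tuple(g.get("minima_range", (2, 8))))
        else:
            raise ConfigError("analytic backend needs pes_json or generate")
        return pes, pes.dim, molecule, None, pes
    if molecule is None:
        raise ConfigError(f"backend {kind!r} requires a molecule")
    if kind == "mmff":
        calc = calculators.MMFFCalculator(
            molecule.elements, molecule.coords,
            charge=int(backend.get("charge", 0)))
    elif kind == "file_exchange":
        calc = calculators.FileExchangeCalculator(
            backend.get("workdir", "."), molecule.elements,
            want_forces=bool(backend.get("forces", False)),
            timeout=float(backend.get("timeout", 60.0)))
    else:
        raise ConfigError(f"unknown backend kind {kind!r}")
    fn = calculators.torsion_energy_function(molecule, calc)
    return fn, molecule.n_torsions, molecule, calc, None


def _relax_torsion_space(pes, torsions):
    """Local minimization of the true analytic PES over torsions."""

    def fun(t):
        return pes.energy(t), pes.gradient(t)

    res = _scipy_minimize(fun, np.asarray(torsions, float), jac=True,
                          method="L-BFGS-B", options={"maxiter": 500})
    return np.atleast_1d(wrap_angle(res.x)), float(res.fun)


def run_pipeline(config) -> RunManifest:
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    outdir = cfg.get("output_dir", "torsbo_run")
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed,
                           started=datetime.datetime.now().isoformat())
    manifest_path = os.path.join(outdir, "manifest.json")

    try:
        energy_fn, dim, molecule, calc, true_pes = _build_backend(cfg)
        scfg_d = dict(cfg.get("search", {}) or {})
        scfg = search.SearchConfig(
            budget=int(cfg.get("budget", scfg_d.pop("budget", 50))),
            e_cut=float(cfg.get("e_cut", scfg_d.pop("e_cut", 2.0))),
            seed=seed, **scfg_d)

        # -- stage 1: BO search ------------------------------------------
        trace, samples = search.run_search(energy_fn, dim, scfg)
        trace_path = os.path.join(outdir, "trace.csv")
        trace.to_dataframe().to_csv(trace_path, index=False)
        with open(os.path.join(outdir, "search_summary.json"), "w") as fh:
            json.dump(trace.summary(), fh, indent=1)
        manifest.outputs["trace"] = trace_path
        manifest.counts["acquisitions"] = trace.n_iterations
        manifest.completed_stages.append("search")

        # -- stage 2: minima extraction + purge --------------------------
        model = trace._model
        cands = minima_mod.extract_minima(model)
        pcfg = cfg.get("purge", {}) or {}
        purged = minima_mod.purge_duplicates(
            cands, d_tol=float(pcfg.get("d_tol", minima_mod.D_TOL_DEFAULT)),
            E_tol=float(pcfg.get("e_tol", minima_mod.E_TOL_DEFAULT)))
        minima_path = os.path.join(outdir, "minima.csv")
        minima_mod.minima_to_dataframe(purged).to_csv(minima_path, index=False)
        manifest.outputs["minima"] = minima_path
        manifest.counts["minima_found"] = len(cands)
        manifest.counts["minima_after_purge"] = len(purged)
        manifest.completed_stages.append("minima")
        if molecule is not None:
            mxyz = os.path.join(outdir, "minima.xyz")
            for k, cand in enumerate(purged):
                write_xyz(mxyz, molecule.elements,
                          molecule.set_torsions(cand.torsions),
                          comment=f"minimum {k} surrogate E={cand.energy:.6f}",
                          append=k > 0)
            manifest.outputs["minima_xyz"] = mxyz

        # -- stage 3: refinement -----------------------------------------
        rcfg = cfg.get("refine", {}) or {}
        max_conf = int(rcfg.get("max_conformers", 15))
        temperature = float(rcfg.get("temperature", 300.0))
        records = []
        n_relax = 0
        selected = purged[:max_conf]
        for k, cand in enumerate(selected):
            rec = refine.ConformerRecord(label=f"c{k:03d}",
                                         search_energy=cand.energy,
                                         temperature=temperature)
            if true_pes is not None:
                tors, e_opt = _relax_torsion_space(true_pes, cand.torsions)
                rec.e_opt = e_opt
                rec.geometry = tors
                n_relax += 1
            elif calc is not None and getattr(calc, "provides_forces", False) \
                    and rcfg.get("enabled", True):
                geom0 = molecule.set_torsions(cand.torsions)
                geom, e_opt = refine.relax_structure(
                    calc, geom0, fmax=float(rcfg.get("fmax",
                                                     refine.FMAX_DEFAULT)))
                rec.geometry = geom
                rec.e_opt = e_opt
                n_relax += 1
                if rcfg.get("vibrations", True):
                    H = refine.hessian_finite_difference(
                        calc, geom, molecule.masses,
                        delta=float(rcfg.get("delta", refine.DELTA_DEFAULT)))
                    vib = refine.normal_modes(H, geom, molecule.masses)
                    rec.zpe = vib.zero_point_energy
                    rec.f_vib = vib.free_energy(temperature)
            records.append(rec)
        manifest.counts["relaxations"] = n_relax
        manifest.completed_stages.append("refine")

        # -- stage 4: optional high-level deltas + hierarchy -------------
        if cfg.get("deltas_csv"):
            import pandas as pd
            tbl = pd.read_csv(cfg["deltas_csv"])
            mapping = dict(zip(tbl.iloc[:, 0].astype(str), tbl.iloc[:, 1]))
            refine.apply_singlepoint_delta(records, mapping)
        hier = refine.assemble_hierarchy(records)
        hier_csv = os.path.join(outdir, "hierarchy.csv")
        hier.to_csv(hier_csv, index=False)
        hier.to_json(os.path.join(outdir, "hierarchy.json"), orient="records",
                     indent=1)
        manifest.outputs["hierarchy"] = hier_csv
        manifest.completed_stages.append("rank")
    finally:
        manifest.finished = datetime.datetime.now().isoformat()
        manifest.write(manifest_path)
        manifest.outputs["manifest"] = manifest_path
    return manifest
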