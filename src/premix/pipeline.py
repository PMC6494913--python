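"""Pipeline orchestration: simulate → extract → pool → fit → map.

A single YAML config drives every stage; each stage is a pure function of
(inputs, config, seed) and writes its outputs under the run directory.  The
run report records package versions, seeds, per-stage fit quality and a
SHA-256 manifest chaining inputs to outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .density import GridSpec, compute_map, contour_report, write_ccp4, write_dx
from .ensemble import FitConfig, PREEnsembleModel
from .forward import PREModelParams, read_gamma2_matrix, write_gamma2_matrix
from .io import write_coords_pdb, write_pool
from .peaks import (
    HMQCSettings,
    gamma2_from_table,
    read_gamma2_table,
    read_peak_table,
    write_gamma2_table,
)
from .synthetic import (
    TOY_TAU_C,
    NoiseModel,
    ToyConfig,
    make_pool_with_truth,
    make_toy_system,
    simulate_observed,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything a reproducible run needs; see the YAML keys of each block."""

    seed: int = 0
    outdir: str = "premix_run"
    # synthetic system (the pipeline's data source when no experimental
    # tables are supplied)
    toy: ToyConfig = field(default_factory=ToyConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_decoys: int = 2000
    fingerprint_floor: float = 0.05
    write_pool_pdb: bool = False
    # physics (the default correlation time matches the synthetic system; set
    # tau_c explicitly when analyzing experimental tables)
    hmqc: HMQCSettings = field(default_factory=HMQCSettings)
    pre: PREModelParams = field(
        default_factory=lambda: PREModelParams(tau_c=TOY_TAU_C)
    )
    gamma2_cap: float = 80.0
    noise_floor: float = 3.0
    # fitting
    fit: FitConfig = field(default_factory=FitConfig)
    n_map_ensembles: int = 3
    # density map
    voxel_size: float = 2.0
    contour_level: float = 0.05
    # optional experimental inputs (site -> intensity table path); when set,
    # the extract/fit stages use these instead of simulated tables
    intensity_tables: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def sub(klass, key):
            return klass(**d.get(key, {})) if isinstance(d.get(key, {}), dict) else d[key]

        kwargs = {k: v for k, v in d.items()
                  if k in {f.name for f in fields(cls)}
                  and k not in {"toy", "noise", "hmqc", "pre", "fit"}}
        return cls(
            toy=sub(ToyConfig, "toy"),
            noise=sub(NoiseModel, "noise"),
            hmqc=sub(HMQCSettings, "hmqc"),
            pre=sub(PREModelParams, "pre"),
            fit=sub(FitConfig, "fit"),
            **kwargs,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Stateful helper executing the stages against one run directory."""

    def __init__(self, cfg: PipelineConfig, outdir: str | None = None,
                 seed: int | None = None, log=print):
        self.cfg = cfg
        if seed is not None:
            cfg.seed = seed
            cfg.fit = FitConfig(**{**asdict(cfg.fit), "seed": seed})
        self.outdir = Path(outdir or cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.log = log
        self.manifest: dict[str, str] = {}
        self.report: dict = {
            "versions": {
                "premix": __version__,
                "python": sys.version.split()[0],
                "numpy": np.__version__,
            },
            "seed": cfg.seed,
            "stages": {},
        }
        self._system = None
        self._pool = None
        self._matrix = None
        self._observed = None
        self._results = None

    # -- internals ---------------------------------------------------------
    def _register(self, *paths) -> None:
        for p in paths:
            p = Path(p)
            self.manifest[str(p.relative_to(self.outdir))] = _sha256(p)

    @property
    def system(self):
        if self._system is None:
            self._system = make_toy_system(
                self.cfg.toy, seed=self.cfg.seed, params=self.cfg.pre
            )
        return self._system

    # -- stages ------------------------------------------------------------
    def simulate(self) -> dict[str, Path]:
        """Write per-site intensity tables (and truth records) from the toy system."""
        import pandas as pd

        self.log("stage simulate: generating toy system and intensity tables")
        tables = simulate_observed(
            self.system, self.cfg.pre, self.cfg.hmqc, self.cfg.noise,
            seed=self.cfg.seed,
        )
        paths = {}
        for site, records in tables.items():
            p = self.outdir / f"intensity_{site}.tsv"
            pd.DataFrame(
                [
                    {
                        "methyl_id": r.methyl_id,
                        "I_para": r.I_para,
                        "I_dia": r.I_dia,
                        "sigma_para": r.sigma_para,
                        "sigma_dia": r.sigma_dia,
                        "R2_diaH": r.R2_diaH,
                        "R2_diaHC": r.R2_diaHC,
                    }
                    for r in records
                ]
            ).to_csv(p, sep="\t", index=False)
            paths[site] = p
        truth_path = self.outdir / "truth_weights.tsv"
        pd.DataFrame(
            {
                "truth_index": np.arange(len(self.system.truth_weights)),
                "weight": self.system.truth_weights,
            }
        ).to_csv(truth_path, sep="\t", index=False)
        receptor = self.outdir / "receptor_frame.pdb"
        write_coords_pdb(self.system.receptor_atoms, receptor, res_name="FIX")
        self._register(*paths.values(), truth_path, receptor)
        self.report["stages"]["simulate"] = {
            "sites": sorted(paths), "n_probes": len(self.system.probe_ids)
        }
        return paths

    def extract(self, intensity_paths: dict[str, Path] | None = None) -> dict[str, Path]:
        """Invert intensity tables to per-site Γ₂ tables."""
        self.log("stage extract: inverting intensity ratios to Γ₂")
        paths = intensity_paths or {
            site: Path(p) for site, p in self.cfg.intensity_tables.items()
        }
        if not paths:
            paths = {
                site: self.outdir / f"intensity_{site}.tsv"
                for site in self.system.site_ids
            }
        observed = []
        out_paths = {}
        for site, p in sorted(paths.items()):
            if not Path(p).exists():
                raise FileNotFoundError(f"extract: missing intensity table {p}")
            records = read_peak_table(p)
            gset = gamma2_from_table(
                records, site, self.cfg.hmqc,
                gamma2_cap=self.cfg.gamma2_cap, noise_floor=self.cfg.noise_floor,
            )
            op = self.outdir / f"gamma2_{site}.tsv"
            write_gamma2_table(gset, op)
            observed.append(gset)
            out_paths[site] = op
        self._observed = observed
        self._register(*out_paths.values())
        self.report["stages"]["extract"] = {
            "n_ok": int(sum(len(g.ok_entries()) for g in observed)),
            "n_total": int(sum(len(g) for g in observed)),
        }
        return out_paths

    def pool(self) -> Path:
        """Generate the candidate pool and its back-calculated Γ₂ matrix."""
        self.log(f"stage pool: sampling {self.cfg.n_decoys} decoys + truth")
        pool, truth_idx, matrix = make_pool_with_truth(
            self.system, self.cfg.n_decoys, self.cfg.pre,
            seed=self.cfg.seed, fingerprint_floor=self.cfg.fingerprint_floor,
        )
        self._pool, self._matrix = pool, matrix
        mpath = self.outdir / "gamma2_matrix.tsv"
        write_gamma2_matrix(matrix, mpath)
        written = [mpath]
        if self.cfg.write_pool_pdb:
            pdb = self.outdir / "pool.pdb"
            side = self.outdir / "pool_sites.tsv"
            idx = self.outdir / "pool_index.tsv"
            write_pool(pool, pdb, side, idx)
            written += [pdb, side, idx]
        self._register(*written)
        self.report["stages"]["pool"] = {
            "n_members": int(len(pool)), "n_truth": int(len(truth_idx))
        }
        return mpath

    def fit(self, matrix_path: Path | None = None,
            gamma2_paths: dict[str, Path] | None = None):
        """Best-single-structure fit and stepwise ensemble reweighting."""
        self.log("stage fit: optimizing ensemble weights")
        if self._matrix is None or matrix_path is not None:
            self._matrix = read_gamma2_matrix(matrix_path or self.outdir / "gamma2_matrix.tsv")
        if self._observed is None or gamma2_paths is not None:
            paths = gamma2_paths or {
                site: self.outdir / f"gamma2_{site}.tsv"
                for site in self.system.site_ids
            }
            self._observed = [
                read_gamma2_table(p, site) for site, p in sorted(paths.items())
            ]
        model = PREEnsembleModel(self._observed, self._matrix)
        single = model.fit(method="single")
        results = model.fit(method="hierarchical", config=self.cfg.fit)
        self._results = results
        wpath = self.outdir / "weights.tsv"
        rpath = self.outdir / "fit_report.json"
        results.save(wpath, rpath)
        ovc = self.outdir / "observed_vs_calc.tsv"
        results.observed_vs_calc().to_csv(ovc, sep="\t")
        self._register(wpath, rpath, ovc)
        self.report["stages"]["fit"] = {
            "q_single_best": single.q_ens,
            "q_ens": results.q_ens,
            "per_site_q": {k: float(v) for k, v in results.per_site_q().items()},
            "n_active": results.n_active,
        }
        return results

    def map(self) -> Path:
        """Reweighted atomic probability density of the mobile partner."""
        self.log("stage map: computing reweighted atomic probability density")
        if self._results is None:
            raise RuntimeError("map stage requires a completed fit stage")
        if self._pool is None:
            raise RuntimeError("map stage requires the in-memory pool")
        ensembles = []
        base = self._results
        ens_list = [base.ensemble]
        for i in range(1, self.cfg.n_map_ensembles):
            cfg_i = FitConfig(**{**asdict(self.cfg.fit), "seed": self.cfg.fit.seed + i})
            model = PREEnsembleModel(self._observed, self._matrix)
            ens_list.append(model.fit(method="hierarchical", config=cfg_i).ensemble)
        for ens in ens_list:
            coords = [self._pool[int(k)].atoms for k in ens.member_ids]
            ensembles.append((ens.weights, coords))
        all_coords = np.concatenate(
            [c for _, coords in ensembles for c in coords]
        )
        grid = GridSpec.around(all_coords, self.cfg.voxel_size,
                               padding=4.0 * self.cfg.voxel_size)
        dmap = compute_map(ensembles, grid, normalization="unit_max",
                           kernel_cutoff_sigmas=6.0)
        paths = []
        ccp4 = self.outdir / "density_unitmax.ccp4"
        write_ccp4(dmap, ccp4)
        dx = self.outdir / "density_unitmax.dx"
        write_dx(dmap, dx)
        dmap_int = dmap.normalized("unit_integral")
        dx_int = self.outdir / "density_unitintegral.dx"
        write_dx(dmap_int, dx_int)
        rep = contour_report(dmap, self.cfg.contour_level)
        cpath = self.outdir / "contour_report.json"
        with open(cpath, "w") as fh:
            json.dump(rep, fh, indent=2)
        paths += [ccp4, dx, dx_int, cpath]
        self._register(*paths)
        self.report["stages"]["map"] = {
            "grid_dims": list(grid.dims),
            "contour": rep,
            "n_ensembles": len(ensembles),
        }
        return ccp4

    def finish(self) -> Path:
        self.report["manifest"] = self.manifest
        rpath = self.outdir / "run_report.json"
        with open(rpath, "w") as fh:
            json.dump(self.report, fh, indent=2)
        return rpath


def run_pipeline(cfg: PipelineConfig, outdir: str | None = None,
                 seed: int | None = None, log=print) -> dict:
    """Execute the full pipeline; returns the run report dict.

    Stages: simulate (when no experimental tables are configured) → extract →
    pool → fit → map.  Any stage error aborts the run with the stage name in
    the exception message.
    """
    run = PipelineRun(cfg, outdir=outdir, seed=seed, log=log)
    stages = []
    if not cfg.intensity_tables:
        stages.append(("simulate", run.simulate))
    stages += [("extract", run.extract), ("pool", run.pool),
               ("fit", run.fit), ("map", run.map)]
    for name, fn in stages:
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    run.finish()
    return run.report
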