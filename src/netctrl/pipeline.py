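"""Run configuration and end-to-end pipeline orchestration.

Stages, in order: transition-energy matrix -> asymmetry / relay /
variability statistics -> rewired-network null comparison -> spin-null
modulation screens -> predictor analysis.  All outputs are tab-separated
tables plus a JSON manifest recording parameters, seeds and per-stage
runtimes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from .model import StateTransitionModel
from .nulls import build_null_ensemble, compare_empirical_vs_nulls
from .predictors import predictor_report
from .spatial import screen_modulation_map, spin_permutations

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run.

    Defaults follow the main analysis settings: T=1, rho=1, c=0, alpha=0.05.
    """

    connectome: str = ""
    regions: str = ""
    states: str = ""
    modulation_maps: dict = field(default_factory=dict)  # name -> {path, mode}
    hierarchy_map: str = ""
    T: float = 1.0
    rho: float = 1.0
    c: float = 0.0
    n_steps: int = 1000
    n_perm: int = 10_000
    n_rot: int = 200
    n_nulls: int = 100
    alpha: float = 0.05
    seed: int = 0
    unit_norm: bool = False
    control_mode: str = "uniform"
    null_kinds: tuple = ("degree_preserving", "geometry_preserving")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.null_kinds, list):
            cfg.null_kinds = tuple(cfg.null_kinds)
        return cfg

    def validate(self) -> None:
        for name, path in [
            ("connectome", self.connectome),
            ("regions", self.regions),
            ("states", self.states),
        ]:
            if not path:
                raise ValueError(f"config missing required path: {name}")
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if self.T <= 0 or self.rho <= 0 or self.c < 0:
            raise ValueError("require T > 0, rho > 0, c >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full analysis; returns the artifact directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(rng.integers(0, 2**31 - 1))
        for name in ("stats", "nulls", "spin", "predictors")
    }
    manifest = {
        "config": {**asdict(config), "null_kinds": list(config.null_kinds)},
        "stage_seeds": stage_seeds,
        "runtimes_s": {},
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)
        log.info("stage: %s", name)
        return time.perf_counter()

    try:
        t0 = stage("energy")
        conn = nio.read_connectome(config.connectome, config.regions)
        states = nio.read_state_table(config.states, region_labels=conn.labels)
        if config.unit_norm:
            from .energy import StateMap

            states = [
                StateMap(values=s.values, label=s.label, unit_norm=True) for s in states
            ]
        model = StateTransitionModel(conn, states, control_mode=config.control_mode)
        res = model.fit(
            T=config.T, rho=config.rho, c=config.c, n_steps=config.n_steps
        )
        res.to_table(out / "transition_energy.tsv")
        manifest["runtimes_s"]["energy"] = time.perf_counter() - t0

        t0 = stage("stats")
        asym = res.asymmetry()
        nio.write_matrix_table(out / "asymmetry_delta.tsv", asym.delta, asym.state_labels)
        rel = res.relay()
        vt = res.variability_test(n_perm=config.n_perm, seed=stage_seeds["stats"])
        rho_d, p_d = res.distance_energy_relation()
        stats_summary = {
            "variability": {"t": vt.t, "p": vt.p, "cohens_d": vt.cohens_d},
            "relayed_fraction": rel.relayed_fraction,
            "distance_energy": {"spearman_rho": rho_d, "p": p_d},
            "reach_minus_leave": dict(
                zip(asym.state_labels, asym.reach_minus_leave.tolist())
            ),
        }
        (out / "stats.json").write_text(json.dumps(stats_summary, indent=2))
        manifest["runtimes_s"]["stats"] = time.perf_counter() - t0

        t0 = stage("nulls")
        null_summary = {}
        for kind in config.null_kinds:
            ens = build_null_ensemble(
                conn, kind, config.n_nulls, seed=stage_seeds["nulls"]
            )
            cmp_ = compare_empirical_vs_nulls(
                conn,
                ens,
                states,
                model.weights,
                T=config.T,
                rho=config.rho,
                c=config.c,
                n_steps=config.n_steps,
            )
            null_summary[kind] = {
                "empirical_mean_energy": cmp_.empirical_mean_energy,
                "null_mean_energies": cmp_.null_mean_energies.tolist(),
                "p_lower": cmp_.p_lower,
                "n_failed": cmp_.n_failed,
            }
        (out / "nulls.json").write_text(json.dumps(null_summary, indent=2))
        manifest["runtimes_s"]["nulls"] = time.perf_counter() - t0

        if config.modulation_maps:
            t0 = stage("spin_screen")
            if conn.sphere_coords is None:
                raise ValueError("spin screen requires sphere coordinates (sx/sy/sz)")
            spin = spin_permutations(
                conn.sphere_coords,
                conn.hemisphere,
                n_rot=config.n_rot,
                seed=stage_seeds["spin"],
            )
            screen_rows = {}
            from .graph import normalize_adjacency

            system = normalize_adjacency(conn, c=config.c)
            for name, spec in config.modulation_maps.items():
                mmap, _ = nio.read_matrix_table(spec["path"])
                screen = screen_modulation_map(
                    system,
                    states,
                    mmap[:, 0],
                    spec["mode"],
                    spin,
                    T=config.T,
                    rho=config.rho,
                    n_steps=config.n_steps,
                    alpha=config.alpha,
                )
                screen_rows[name] = (
                    screen.pct_facilitated - screen.pct_disfacilitated
                ).tolist()
            import pandas as pd

            pd.DataFrame(
                screen_rows, index=[s.label for s in states]
            ).T.to_csv(out / "spin_screen.tsv", sep="\t", index_label="map")
            manifest["runtimes_s"]["spin_screen"] = time.perf_counter() - t0

        t0 = stage("predictors")
        if config.hierarchy_map:
            hierarchy, _ = nio.read_matrix_table(config.hierarchy_map)
            hierarchy = hierarchy[:, 0]
        else:
            hierarchy = np.zeros(conn.n)
        if np.ptp(hierarchy) > 0:
            from .predictors import state_predictor_table

            table = state_predictor_table(states, conn, hierarchy, res.te)
            table.to_csv(out / "predictors.tsv", sep="\t")
            try:
                rep = predictor_report(states, conn, hierarchy, res.te)
                (out / "predictors.json").write_text(
                    json.dumps(
                        {
                            "partials": rep.partials.to_dict(),
                            "dominance": rep.dominance.to_dict(),
                            "r_squared": rep.r_squared,
                        },
                        indent=2,
                    )
                )
            except ValueError as exc:
                # too few states for partials/dominance: table only
                log.info("predictor partials/dominance skipped: %s", exc)
                manifest["predictors_note"] = str(exc)
        manifest["runtimes_s"]["predictors"] = time.perf_counter() - t0
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else None
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    (out / "summary.txt").write_text(res.summary(n_perm=min(config.n_perm, 1000), seed=config.seed))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
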