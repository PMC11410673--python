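"""Model/Results interface over the transition-energy analysis.

``StateTransitionModel`` bundles a connectome and a set of activation
topographies; ``fit()`` normalizes the adjacency, computes the all-to-all
optimal-energy matrix and returns a ``StateTransitionResults`` object from
which the downstream statistics (asymmetry, variability, relays, the
energy-distance relation, predictor analyses) and writers hang.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import io as nio
from .energy import (
    ControlWeights,
    StateMap,
    TransitionEnergyMatrix,
    build_control_weights,
    transition_energy_matrix,
)
from .graph import Connectome, NormalizedSystem, normalize_adjacency
from .stats import (
    AsymmetryReport,
    PermutationTestResult,
    RelayReport,
    asymmetry_measures,
    distance_energy_relation,
    relay_analysis,
    variability_test,
)

__all__ = ["StateTransitionModel", "StateTransitionResults"]


class StateTransitionModel:
    """Optimal-control transition model on a structural connectome.

    Parameters
    ----------
    connectome
        The structural network whose (normalized) adjacency drives the
        linear dynamics.
    states
        Activation topographies acting as sources and targets.
    control_mode, control_map
        Specification of the diagonal input matrix B (see
        :func:`netctrl.energy.build_control_weights`).
    """

    def __init__(
        self,
        connectome: Connectome,
        states: list[StateMap],
        control_mode: str = "uniform",
        control_map: np.ndarray | None = None,
    ):
        if not states:
            raise ValueError("need at least one state")
        for s in states:
            if s.n != connectome.n:
                raise ValueError(
                    f"state {s.label!r} has {s.n} regions, connectome has {connectome.n}"
                )
        self.connectome = connectome
        self.states = list(states)
        self.weights: ControlWeights = build_control_weights(
            control_mode, control_map, n=connectome.n
        )

    @classmethod
    def from_tables(
        cls,
        connectome_path,
        region_path,
        state_path,
        control_mode: str = "uniform",
        control_map: np.ndarray | None = None,
    ) -> "StateTransitionModel":
        conn = nio.read_connectome(connectome_path, region_path)
        states = nio.read_state_table(state_path, region_labels=conn.labels)
        return cls(conn, states, control_mode, control_map)

    def fit(
        self,
        T: float = 1.0,
        rho: float = 1.0,
        c: float = 0.0,
        c_relative: bool = False,
        n_steps: int = 1000,
    ) -> "StateTransitionResults":
        system = normalize_adjacency(self.connectome, c=c, relative=c_relative)
        te = transition_energy_matrix(
            system, self.weights, self.states, T=T, rho=rho, n_steps=n_steps
        )
        return StateTransitionResults(model=self, system=system, te=te)


@dataclass
class StateTransitionResults:
    """Fitted transition-energy table with its derived statistics."""

    model: StateTransitionModel
    system: NormalizedSystem
    te: TransitionEnergyMatrix
    _asym: AsymmetryReport | None = field(default=None, repr=False)

    @property
    def energies(self) -> np.ndarray:
        return self.te.energies

    def asymmetry(self) -> AsymmetryReport:
        if self._asym is None:
            self._asym = asymmetry_measures(self.te)
        return self._asym

    def relay(self) -> RelayReport:
        return relay_analysis(self.te)

    def variability_test(
        self, n_perm: int = 10_000, seed: int | None = None
    ) -> PermutationTestResult:
        return variability_test(self.te, n_perm=n_perm, seed=seed)

    def distance_energy_relation(self) -> tuple[float, float]:
        return distance_energy_relation(self.model.states, self.te)

    def to_table(self, path) -> None:
        nio.write_energy_matrix(path, self.te)

    def summary(self, n_perm: int = 1000, seed: int = 0) -> str:
        """Plain-text summary of the fitted transition-energy analysis."""
        te = self.te
        p = te.params
        asym = self.asymmetry()
        rel = self.relay()
        lines = [
            "State Transition Energy Results",
            "=" * 47,
            f"regions:            {self.model.connectome.n}",
            f"states:             {len(self.model.states)}",
            f"control mode:       {self.model.weights.mode}",
            f"T={p.get('T')}  rho={p.get('rho')}  c={p.get('c'):.4g}  n_steps={p.get('n_steps')}",
            "-" * 47,
            f"mean energy:        {self._offdiag().mean():.6g}",
            f"energy range:       [{self._offdiag().min():.6g}, {self._offdiag().max():.6g}]",
            f"mean source s.d.:   {asym.source_sd.mean():.6g}",
            f"mean target s.d.:   {asym.target_sd.mean():.6g}",
            f"relayed fraction:   {rel.relayed_fraction:.3f}",
        ]
        if len(self.model.states) >= 3:
            rho_ds, p_ds = self.distance_energy_relation()
            vt = self.variability_test(n_perm=n_perm, seed=seed)
            lines += [
                f"energy~distance:    Spearman rho={rho_ds:.3f} (p={p_ds:.2g})",
                f"target>source s.d.: t={vt.t:.2f}, p={vt.p:.3g}, d={vt.cohens_d:.2f}",
            ]
        lines.append("=" * 47)
        return "\n".join(lines)

    def _offdiag(self) -> np.ndarray:
        e = self.te.energies
        if e.shape[0] == e.shape[1]:
            return e[~np.eye(e.shape[0], dtype=bool)]
        return e.ravel()
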