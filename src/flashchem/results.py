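"""Yield curves and experiment result containers.

The chemical yield G(t) = N(t)/E x 100 [molecules/100 eV] normalises the
instantaneous species count N(t) by the cumulative deposited energy E(t)
of all protons injected so far; it is an intensity quantity, so the CDR
yield does not depend on how many (independent) protons are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .species import N_SPECIES, SPECIES_LABELS, SpeciesKind


def make_recording_grid(t_end_ps: float, record_every_ps: float = 2.0,
                        log_points: int | None = None) -> np.ndarray:
    """Recording grid over [0, t_end]: uniform, or log-spaced from 1 ps.

    The uniform grid with the 2 ps default matches the engine's native
    recording resolution; the log grid resolves both the picosecond spur
    chemistry and the microsecond tail with few points.
    """
    if t_end_ps <= 0:
        raise ValueError("t_end_ps must be positive")
    if log_points is not None:
        grid = np.geomspace(1.0, t_end_ps, log_points)
        return np.unique(np.concatenate([[0.0], grid, [t_end_ps]]))
    n = int(np.floor(t_end_ps / record_every_ps + 1e-9))
    grid = np.arange(n + 1) * record_every_ps
    if grid[-1] < t_end_ps - 1e-9:
        grid = np.append(grid, t_end_ps)
    return grid


@dataclass(frozen=True)
class GCurve:
    """Time series of species counts and G values on a recording grid."""

    times_ps: np.ndarray
    counts: np.ndarray           # (T, N_SPECIES)
    energy_ev: np.ndarray        # cumulative deposited energy E(t)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ps)
        if np.any(np.diff(t) <= 0):
            raise ValueError("recording times must be strictly increasing")
        if self.counts.shape != (t.size, N_SPECIES):
            raise ValueError("counts must have shape (T, n_species)")
        if self.energy_ev.shape != (t.size,):
            raise ValueError("energy_ev must have shape (T,)")

    def g(self, species: SpeciesKind) -> np.ndarray:
        """G(t) for one species; NaN wherever no energy is deposited yet."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(self.energy_ev > 0,
                           self.counts[:, int(species)] / self.energy_ev * 100.0,
                           np.nan)
        return out

    def endpoint_g(self, species: SpeciesKind) -> float:
        return float(self.g(species)[-1])

    @property
    def deposited_energy_ev(self) -> float:
        return float(self.energy_ev[-1])

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"time_ps": self.times_ps}
        order = [SpeciesKind.E_HYDRATED, SpeciesKind.OH_RADICAL,
                 SpeciesKind.H_RADICAL, SpeciesKind.H2O2,
                 SpeciesKind.H3O_PLUS, SpeciesKind.OH_MINUS, SpeciesKind.H2]
        for kind in order:
            cols[f"n_{SPECIES_LABELS[kind]}"] = self.counts[:, int(kind)]
        cols["E_eV"] = self.energy_ev
        for kind in order:
            cols[f"G_{SPECIES_LABELS[kind]}"] = self.g(kind)
        return pd.DataFrame(cols)


def gcurve_from_history(history, grid_ps: np.ndarray) -> GCurve:
    counts, energy = history.sample(grid_ps)
    return GCurve(times_ps=np.asarray(grid_ps, dtype=float),
                  counts=counts, energy_ev=energy)


#: Species whose yields are routinely reported.
REPORTED_SPECIES = (SpeciesKind.E_HYDRATED, SpeciesKind.OH_RADICAL,
                    SpeciesKind.H_RADICAL, SpeciesKind.H2O2)


@dataclass(frozen=True)
class ExperimentResult:
    """Aggregated repeats of one scenario.

    Endpoint statistics are over repeats; ``relative_uncertainty`` is the
    standard error of the mean divided by the mean (the uncertainty of
    the reported mean yield), quoted for the hydroxyl radical.
    """

    curves: tuple[GCurve, ...]
    scenario: dict = field(default_factory=dict)

    @property
    def n_repeats(self) -> int:
        return len(self.curves)

    def endpoint_values(self, species: SpeciesKind) -> np.ndarray:
        return np.array([c.endpoint_g(species) for c in self.curves])

    def endpoint_mean(self, species: SpeciesKind) -> float:
        return float(self.endpoint_values(species).mean())

    def endpoint_sd(self, species: SpeciesKind) -> float:
        """Sample SD across repeats (NaN for a single repeat)."""
        vals = self.endpoint_values(species)
        if vals.size < 2:
            return float("nan")
        return float(vals.std(ddof=1))

    def endpoint_sem(self, species: SpeciesKind) -> float:
        vals = self.endpoint_values(species)
        if vals.size < 2:
            return float("nan")
        return float(vals.std(ddof=1) / np.sqrt(vals.size))

    def relative_uncertainty(self,
                             species: SpeciesKind = SpeciesKind.OH_RADICAL
                             ) -> float:
        return self.endpoint_sem(species) / self.endpoint_mean(species)

    def summary(self) -> dict:
        out = {"scenario": dict(self.scenario), "n_repeats": self.n_repeats,
               "species": {}}
        for kind in REPORTED_SPECIES:
            out["species"][SPECIES_LABELS[kind]] = {
                "g_mean": self.endpoint_mean(kind),
                "g_sd": self.endpoint_sd(kind),
                "g_sem": self.endpoint_sem(kind),
            }
        out["relative_uncertainty_OH"] = self.relative_uncertainty()
        return out


@dataclass(frozen=True)
class YieldComparison:
    """Endpoint yields under CDR and UHDR with their relative change.

    delta_g_percent = 100 (G_UHDR - G_CDR) / G_CDR; negative values mean
    the UHDR condition reduces the yield.
    """

    g_cdr: dict[SpeciesKind, float]
    g_uhdr: dict[SpeciesKind, float]
    delta_g_percent: dict[SpeciesKind, float]
    delta_g_sd_percent: dict[SpeciesKind, float]


def compare_yields(cdr: ExperimentResult, uhdr: ExperimentResult,
                   match_keys: tuple[str, ...] = ("energy_mev",)
                   ) -> YieldComparison:
    """Relative yield change UHDR vs CDR with propagated SD.

    Scenarios must agree on the matching keys (proton energy by default);
    otherwise the comparison is meaningless and an error is raised.
    """
    for key in match_keys:
        a = cdr.scenario.get(key)
        b = uhdr.scenario.get(key)
        if a != b:
            raise ValueError(f"cannot compare: scenario {key!r} differs "
                             f"({a!r} vs {b!r})")
    g_cdr, g_uhdr, delta, delta_sd = {}, {}, {}, {}
    for kind in REPORTED_SPECIES:
        c, u = cdr.endpoint_mean(kind), uhdr.endpoint_mean(kind)
        g_cdr[kind], g_uhdr[kind] = c, u
        if c == 0 or u == 0:
            delta[kind] = float("nan")
            delta_sd[kind] = float("nan")
            continue
        delta[kind] = 100.0 * (u - c) / c
        sc, su = cdr.endpoint_sem(kind), uhdr.endpoint_sem(kind)
        # first-order propagation on the ratio u/c
        delta_sd[kind] = 100.0 * abs(u / c) * float(
            np.sqrt((su / u) ** 2 + (sc / c) ** 2))
    return YieldComparison(g_cdr=g_cdr, g_uhdr=g_uhdr,
                           delta_g_percent=delta,
                           delta_g_sd_percent=delta_sd)
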