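"""Spur-model surrogate for the physical and physicochemical stages.

A full track-structure code transports the proton and its secondary
electrons event by event through ionisation and excitation cross
sections, then resolves de-excitation channels to produce the ~1 ps
radical distribution.  Both stages are effectively instantaneous relative
to the chemical stage, so this module replaces them with a calibrated
spur model: a monoenergetic proton crossing the ROI depth L deposits
energy in discrete events drawn from a Poisson process of linear density
LET/W (W = mean energy loss per event); each event deposits W and spawns
a localised spur of radicals whose species are drawn from calibrated
1 ps yields and whose positions are Gaussian around the event point.

LET enters only through the event density (and a mild widening of the
spur for sparse, high-energy tracks, mimicking the longer secondary
electron range), so 1 ps yields are LET-independent by construction and
all LET dependence of the final chemistry emerges from spatial density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .beam import ROIGeometry
from .species import SpeciesKind

# ---------------------------------------------------------------------------
# LET table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LETTable:
    """Proton energy [MeV] -> LET [keV/um] with log-log interpolation.

    The built-in points correspond to the entrance (142.4 MeV), plateau
    (50 MeV), pre-Bragg-peak (10 MeV) and Bragg-peak (1 MeV) regions of a
    clinical beam.  No extrapolation outside the tabulated range.
    """

    entries: tuple[tuple[float, float], ...] = (
        (1.0, 40.29),
        (10.0, 4.70),
        (50.0, 1.19),
        (142.4, 0.49),
    )

    def __post_init__(self) -> None:
        e = [p[0] for p in self.entries]
        let = [p[1] for p in self.entries]
        if sorted(e) != e:
            raise ValueError("LET table energies must be ascending")
        if sorted(let, reverse=True) != let:
            raise ValueError("LET must decrease with energy over the table")

    def lookup(self, energy_mev: float) -> float:
        e = np.array([p[0] for p in self.entries])
        let = np.array([p[1] for p in self.entries])
        if not (e[0] <= energy_mev <= e[-1]):
            raise ValueError(
                f"proton energy {energy_mev} MeV outside table range "
                f"[{e[0]}, {e[-1]}] MeV")
        i = int(np.searchsorted(e, energy_mev))
        if math.isclose(energy_mev, e[min(i, e.size - 1)]):
            return float(let[min(i, e.size - 1)])
        if i > 0 and math.isclose(energy_mev, e[i - 1]):
            return float(let[i - 1])
        x0, x1 = math.log(e[i - 1]), math.log(e[i])
        y0, y1 = math.log(let[i - 1]), math.log(let[i])
        f = (math.log(energy_mev) - x0) / (x1 - x0)
        return math.exp(y0 + f * (y1 - y0))


def let_lookup(energy_mev: float, table: LETTable | None = None) -> float:
    """LET [keV/um] for a proton of the given energy [MeV]."""
    return (table or LETTable()).lookup(energy_mev)


# ---------------------------------------------------------------------------
# Track parameters and radical batches
# ---------------------------------------------------------------------------

#: Default 1 ps yields [molecules/100 eV], standard low-LET water
#: radiolysis values for the end of the physicochemical stage.  These are
#: calibration targets for the surrogate, tunable so that single-track
#: 1 us endpoints match reference chemistry.
DEFAULT_INITIAL_G = {
    SpeciesKind.E_HYDRATED: 4.9,
    SpeciesKind.OH_RADICAL: 5.5,
    SpeciesKind.H_RADICAL: 0.62,
    SpeciesKind.H3O_PLUS: 4.9,
    SpeciesKind.OH_MINUS: 0.5,
    SpeciesKind.H2: 0.15,
    SpeciesKind.H2O2: 0.0,
}

#: Reference LET [keV/um] at which the spur width equals its base value;
#: sparser (higher-energy) tracks get wider spurs.
SPREAD_REFERENCE_LET = 40.29


@dataclass(frozen=True)
class TrackParameters:
    """Calibration knobs of the spur surrogate.

    mean_energy_per_event_ev
        W, the mean energy lost per primary interaction event (62.5 eV).
    spur_sigma_base_nm
        Radial Gaussian SD of a spur at the reference LET.
    electron_spread_scale
        Exponent widening the spur as (LET_ref/LET)**scale for sparse
        tracks, standing in for the longer secondary-electron range at
        high proton energy.
    initial_g_values
        1 ps yields per species [molecules/100 eV]; their normalisation
        fixes both the expected particle count per eV and the species
        branching fractions.
    electron_thermalization_factor
        Multiplier on the spur width for hydrated electrons, reflecting
        their thermalization displacement of a few nanometres, well
        beyond the heavy-species spur core.
    cross_section_scale
        Multiplies the event density (sensitivity knob, default 1).
    """

    mean_energy_per_event_ev: float = 62.5
    spur_sigma_base_nm: float = 0.30
    electron_spread_scale: float = 0.20
    electron_thermalization_factor: float = 2.5
    initial_g_values: dict[SpeciesKind, float] = field(
        default_factory=lambda: dict(DEFAULT_INITIAL_G))
    cross_section_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_energy_per_event_ev <= 0:
            raise ValueError("mean_energy_per_event_ev must be positive")
        if self.spur_sigma_base_nm <= 0:
            raise ValueError("spur_sigma_base_nm must be positive")
        if self.cross_section_scale <= 0:
            raise ValueError("cross_section_scale must be positive")
        g = self.initial_g_values
        if any(v < 0 for v in g.values()) or sum(g.values()) <= 0:
            raise ValueError("initial_g_values must be non-negative with "
                             "positive total")

    @property
    def total_g(self) -> float:
        return float(sum(self.initial_g_values.values()))

    @property
    def species_fractions(self) -> dict[SpeciesKind, float]:
        tot = self.total_g
        return {k: v / tot for k, v in self.initial_g_values.items()}

    def spur_sigma_nm(self, let_kev_um: float) -> float:
        return self.spur_sigma_base_nm * (
            SPREAD_REFERENCE_LET / let_kev_um) ** self.electron_spread_scale


@dataclass(frozen=True)
class InitialRadicalBatch:
    """1 ps radical distribution from one proton plus its deposited energy.

    positions are in nm inside the ROI box (already periodically
    wrapped); kinds is the parallel species array; creation time is on
    the chemical-stage clock [ps].
    """

    positions_nm: np.ndarray
    kinds: np.ndarray
    deposited_energy_ev: float
    creation_time_ps: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_nm, dtype=float)
        kinds = np.asarray(self.kinds)
        if pos.shape != (kinds.size, 3):
            raise ValueError("positions must have shape (n, 3) matching kinds")
        if (kinds.size > 0) != (self.deposited_energy_ev > 0):
            raise ValueError("deposited_energy_ev must be positive iff the "
                             "batch is non-empty")

    def __len__(self) -> int:
        return int(np.asarray(self.kinds).size)

    def to_dataframe(self):
        """Debug dump: one row per radical (x_nm, y_nm, z_nm, kind, t_ps)."""
        import pandas as pd

        from .species import SPECIES_LABELS
        pos = np.asarray(self.positions_nm, dtype=float).reshape(-1, 3)
        return pd.DataFrame({
            "x_nm": pos[:, 0], "y_nm": pos[:, 1], "z_nm": pos[:, 2],
            "kind": [SPECIES_LABELS[SpeciesKind(int(k))]
                     for k in np.asarray(self.kinds)],
            "t_ps": self.creation_time_ps,
        })


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def sample_track(energy_mev: float, entry_xy_nm: tuple[float, float],
                 roi: ROIGeometry, params: TrackParameters,
                 rng: np.random.Generator | int,
                 let_table: LETTable | None = None,
                 creation_time_ps: float = 0.0) -> InitialRadicalBatch:
    """Sample the 1 ps radical batch of one proton crossing the ROI.

    The track is a straight line along the beam (z) axis through the
    entry point.  The number of energy-loss events is
    Poisson(LET * L / W); events sit at uniform depths, each deposits W
    and spawns Poisson(W * G_tot / 100) radicals with species drawn from
    the calibrated fractions and positions Gaussian around the event.
    Transverse coordinates are wrapped periodically into the box.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    let = let_lookup(energy_mev, let_table)
    depth_um = roi.depth_um
    if depth_um <= 0:
        return InitialRadicalBatch(np.empty((0, 3)), np.empty(0, dtype=np.int8),
                                   0.0, creation_time_ps)
    w = params.mean_energy_per_event_ev
    mean_events = let * 1.0e3 * depth_um / w * params.cross_section_scale
    n_events = int(rng.poisson(mean_events))
    if n_events == 0:
        return InitialRadicalBatch(np.empty((0, 3)), np.empty(0, dtype=np.int8),
                                   0.0, creation_time_ps)
    z_events = rng.uniform(0.0, roi.depth_nm, size=n_events)
    counts = rng.poisson(w * params.total_g / 100.0, size=n_events)
    n_total = int(counts.sum())
    sigma = params.spur_sigma_nm(let)
    centers = np.column_stack([
        np.full(n_total, entry_xy_nm[0]),
        np.full(n_total, entry_xy_nm[1]),
        np.repeat(z_events, counts),
    ])
    fracs = params.species_fractions
    kinds_list = np.array(list(fracs.keys()), dtype=np.int8)
    probs = np.array(list(fracs.values()))
    kinds = rng.choice(kinds_list, size=n_total, p=probs)
    widths = np.full(n_total, sigma)
    widths[kinds == int(SpeciesKind.E_HYDRATED)] *= \
        params.electron_thermalization_factor
    positions = centers + rng.normal(size=(n_total, 3)) * widths[:, None]
    box = np.array(roi.box_nm)
    positions = np.mod(positions, box)
    return InitialRadicalBatch(positions_nm=positions, kinds=kinds,
                               deposited_energy_ev=float(w * n_events),
                               creation_time_ps=creation_time_ps)


def calibrate_initial_yields(params: TrackParameters,
                             targets: dict[SpeciesKind, float]) -> TrackParameters:
    """Return parameters whose 1 ps yields match ``targets`` in expectation.

    The expected batch yield G = N/E*100 per species equals the stored
    initial_g_values exactly in expectation, so calibration simply
    installs the targets.  Spur geometry is untouched (calibrated
    separately against 1 us single-track endpoints).
    """
    if any(v < 0 for v in targets.values()):
        raise ValueError("target yields must be non-negative")
    if sum(targets.values()) <= 0:
        raise ValueError("target yields must have positive total")
    full = {k: float(targets.get(k, 0.0)) for k in SpeciesKind}
    return replace(params, initial_g_values=full)
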