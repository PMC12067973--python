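"""Step-by-step (SBS) chemical-stage engine.

Every radical is an explicit Brownian particle in a periodic box (the
ROI).  Each step the engine (i) picks an adaptive time step from a fixed
ladder, small when reactive particles are close and large when the
configuration is dilute, (ii) displaces every particle by independent
Gaussian increments with per-axis SD sqrt(2 D dt), wrapping coordinates
periodically, and (iii) executes bimolecular reactions between pairs
whose minimum-image separation falls below the channel's encounter
radius.  Encounter radii follow the Smoluchowski closure
r = k / (4 pi (D1 + D2) N_A), so the dilute well-mixed limit of the
engine reproduces second-order kinetics with the tabulated rate
constants.

Proton injections pause the chemistry: the clock is advanced to the
arrival time by normal stepping, the 1 ps radical batch of the new track
is merged, and stepping resumes; newly merged radicals first react on
the following step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .beam import ROIGeometry
from .constants import AVOGADRO, NM3_PER_LITRE
from .species import N_SPECIES, SpeciesKind
from .track import InitialRadicalBatch

# ---------------------------------------------------------------------------
# Diffusion and reaction tables
# ---------------------------------------------------------------------------

#: Default diffusion coefficients [nm^2/s] of the simulated species.
DEFAULT_DIFFUSION_NM2_S = {
    SpeciesKind.E_HYDRATED: 4.9e9,
    SpeciesKind.OH_RADICAL: 2.8e9,
    SpeciesKind.H3O_PLUS: 9.5e9,
    SpeciesKind.H_RADICAL: 7.0e9,
    SpeciesKind.OH_MINUS: 5.3e9,
    SpeciesKind.H2O2: 2.3e9,
    SpeciesKind.H2: 4.8e9,
}


@dataclass(frozen=True)
class DiffusionCoefficients:
    """Per-species diffusion coefficients [nm^2/s]."""

    values_nm2_s: dict[SpeciesKind, float] = field(
        default_factory=lambda: dict(DEFAULT_DIFFUSION_NM2_S))

    def __post_init__(self) -> None:
        for kind in SpeciesKind:
            if self.values_nm2_s.get(kind, 0.0) < 0:
                raise ValueError(f"diffusion coefficient for {kind.name} "
                                 "must be non-negative")

    def as_array_nm2_ps(self) -> np.ndarray:
        out = np.zeros(N_SPECIES)
        for kind, v in self.values_nm2_s.items():
            out[int(kind)] = v * 1.0e-12
        return out


def reaction_radius(k_per_molar_s: float, d_sum_nm2_s: float) -> float:
    """Smoluchowski encounter radius [nm] for a bimolecular channel.

    Inverts k = 4 pi (D1+D2) r N_A with k in 1/(M s) and the summed
    diffusion coefficient in nm^2/s.
    """
    if k_per_molar_s <= 0 or d_sum_nm2_s <= 0:
        raise ValueError("rate constant and diffusion sum must be positive")
    k_nm3_s = k_per_molar_s * NM3_PER_LITRE / AVOGADRO
    return k_nm3_s / (4.0 * math.pi * d_sum_nm2_s)


@dataclass(frozen=True)
class ReactionChannel:
    reactants: tuple[SpeciesKind, SpeciesKind]
    products: tuple[SpeciesKind, ...]
    rate_constant_per_molar_s: float
    reaction_radius_nm: float

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        lhs = " + ".join(r.name for r in self.reactants)
        rhs = " + ".join(p.name for p in self.products) or "H2O"
        return f"{lhs} -> {rhs} (k={self.rate_constant_per_molar_s:.2e})"


#: Default reaction set: (reactants, products, k [1/(M s)]).  Standard
#: aqueous radiolysis channels at pH 7 without oxygen or scavengers;
#: products consisting only of water are dropped (particles removed).
DEFAULT_REACTIONS: tuple[tuple[tuple[SpeciesKind, SpeciesKind],
                               tuple[SpeciesKind, ...], float], ...] = (
    ((SpeciesKind.E_HYDRATED, SpeciesKind.E_HYDRATED),
     (SpeciesKind.H2, SpeciesKind.OH_MINUS, SpeciesKind.OH_MINUS), 5.5e9),
    ((SpeciesKind.E_HYDRATED, SpeciesKind.OH_RADICAL),
     (SpeciesKind.OH_MINUS,), 3.0e10),
    ((SpeciesKind.E_HYDRATED, SpeciesKind.H3O_PLUS),
     (SpeciesKind.H_RADICAL,), 2.3e10),
    ((SpeciesKind.E_HYDRATED, SpeciesKind.H_RADICAL),
     (SpeciesKind.H2, SpeciesKind.OH_MINUS), 2.5e10),
    ((SpeciesKind.E_HYDRATED, SpeciesKind.H2O2),
     (SpeciesKind.OH_RADICAL, SpeciesKind.OH_MINUS), 1.1e10),
    ((SpeciesKind.OH_RADICAL, SpeciesKind.OH_RADICAL),
     (SpeciesKind.H2O2,), 5.5e9),
    ((SpeciesKind.OH_RADICAL, SpeciesKind.H_RADICAL),
     (), 1.5e10),
    ((SpeciesKind.H_RADICAL, SpeciesKind.H_RADICAL),
     (SpeciesKind.H2,), 5.0e9),
    ((SpeciesKind.H3O_PLUS, SpeciesKind.OH_MINUS),
     (), 1.1e11),
)


class ReactionTable:
    """Bimolecular channels with O(1) lookup by unordered species pair."""

    def __init__(self, channels: list[ReactionChannel]):
        self.channels = list(channels)
        self.channel_matrix = np.full((N_SPECIES, N_SPECIES), -1, dtype=np.int32)
        self.radius_matrix = np.zeros((N_SPECIES, N_SPECIES))
        self.products: list[np.ndarray] = []
        for idx, ch in enumerate(self.channels):
            a, b = int(ch.reactants[0]), int(ch.reactants[1])
            if self.channel_matrix[a, b] != -1:
                raise ValueError(
                    f"duplicate channel for pair {ch.reactants}")
            self.channel_matrix[a, b] = idx
            self.channel_matrix[b, a] = idx
            self.radius_matrix[a, b] = ch.reaction_radius_nm
            self.radius_matrix[b, a] = ch.reaction_radius_nm
            self.products.append(np.array([int(p) for p in ch.products],
                                          dtype=np.int8))
        self.max_radius_nm = max((c.reaction_radius_nm for c in self.channels),
                                 default=0.0)

    @classmethod
    def default(cls, diffusion: DiffusionCoefficients | None = None,
                reactions=DEFAULT_REACTIONS,
                radius_overrides: dict[tuple[SpeciesKind, SpeciesKind], float]
                | None = None) -> "ReactionTable":
        diffusion = diffusion or DiffusionCoefficients()
        dvals = diffusion.values_nm2_s
        channels = []
        for reactants, products, k in reactions:
            a, b = reactants
            key = (a, b)
            if radius_overrides and (key in radius_overrides
                                     or (b, a) in radius_overrides):
                r = radius_overrides.get(key, radius_overrides.get((b, a)))
            else:
                r = reaction_radius(k, dvals[a] + dvals[b])
            channels.append(ReactionChannel(reactants, tuple(products), k, r))
        return cls(channels)


# ---------------------------------------------------------------------------
# Chemical state
# ---------------------------------------------------------------------------


@dataclass
class ChemicalState:
    """Evolving set of diffusing species in the periodic ROI box.

    Arrays are kept compact (``alive`` all true between operations);
    positions live in the half-open box [0, Rx) x [0, Ry) x [0, L).
    """

    positions_nm: np.ndarray
    kinds: np.ndarray
    alive: np.ndarray
    clock_ps: float
    cumulative_deposited_energy_ev: float
    roi: ROIGeometry

    @classmethod
    def empty(cls, roi: ROIGeometry, clock_ps: float = 0.0) -> "ChemicalState":
        return cls(positions_nm=np.empty((0, 3)),
                   kinds=np.empty(0, dtype=np.int8),
                   alive=np.empty(0, dtype=bool),
                   clock_ps=clock_ps,
                   cumulative_deposited_energy_ev=0.0,
                   roi=roi)

    @property
    def n_particles(self) -> int:
        return int(np.count_nonzero(self.alive))

    def counts(self) -> np.ndarray:
        """Per-species particle counts, indexed by SpeciesKind."""
        if self.kinds.size == 0:
            return np.zeros(N_SPECIES, dtype=np.int64)
        return np.bincount(self.kinds[self.alive].astype(np.int64),
                           minlength=N_SPECIES)

    def compact(self) -> None:
        if not self.alive.all():
            keep = self.alive
            self.positions_nm = self.positions_nm[keep]
            self.kinds = self.kinds[keep]
            self.alive = np.ones(self.kinds.size, dtype=bool)


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors to their nearest periodic image."""
    return delta - box * np.round(delta / box)


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def diffuse(state: ChemicalState, dt_ps: float,
            diffusion: DiffusionCoefficients, roi: ROIGeometry,
            rng: np.random.Generator) -> ChemicalState:
    """Displace every live particle by one Brownian step, wrapping PBC.

    Per-axis displacement SD is sqrt(2 D dt); radicals leaving one face
    re-enter through the opposite face.
    """
    if dt_ps <= 0:
        raise ValueError("dt_ps must be positive")
    if state.kinds.size:
        d = diffusion.as_array_nm2_ps()[state.kinds.astype(np.int64)]
        sigma = np.sqrt(2.0 * d * dt_ps)[:, None]
        state.positions_nm += rng.normal(size=state.positions_nm.shape) * sigma
        np.mod(state.positions_nm, np.array(roi.box_nm), out=state.positions_nm)
    return state


def find_pairs(state: ChemicalState, r_query_nm: float,
               mode: str = "tree") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices and minimum-image distances of pairs within ``r_query_nm``.

    ``mode='tree'`` uses a periodic KD-tree; ``mode='brute'`` enumerates
    all pairs (reference implementation for equivalence testing).
    """
    pos = state.positions_nm
    box = np.array(state.roi.box_nm)
    n = pos.shape[0]
    if n < 2:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0)
    if mode == "tree":
        tree = cKDTree(pos, boxsize=box)
        pairs = tree.query_pairs(r_query_nm, output_type="ndarray")
        if pairs.size == 0:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty, np.empty(0)
        i, j = pairs[:, 0], pairs[:, 1]
        delta = minimum_image(pos[i] - pos[j], box)
        d = np.sqrt((delta ** 2).sum(axis=1))
        return i, j, d
    if mode == "brute":
        ii, jj = np.triu_indices(n, k=1)
        delta = minimum_image(pos[ii] - pos[jj], box)
        d = np.sqrt((delta ** 2).sum(axis=1))
        keep = d <= r_query_nm
        return ii[keep], jj[keep], d[keep]
    raise ValueError(f"unknown neighbor-search mode {mode!r}")


def react(state: ChemicalState, table: ReactionTable,
          pairs: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
          r_query_nm: float | None = None, mode: str = "tree",
          reaction_log: list | None = None) -> tuple[int, float]:
    """Execute all due reactions; return (n_reactions, surviving gap).

    Pairs whose minimum-image separation is at or below the channel's
    encounter radius react, closest pair first; each particle reacts at
    most once per step (a particle claimed by a closer pair is no longer
    available to a farther one).  Reactants are removed, products placed
    at the minimum-image pair midpoint.  The returned gap is the minimum
    over surviving reactive pairs of (distance - encounter radius),
    +inf when no reactive pair lies within the query radius; it feeds
    the adaptive step selection.
    """
    if pairs is None:
        rq = r_query_nm if r_query_nm is not None else table.max_radius_nm
        pairs = find_pairs(state, rq, mode=mode)
    i, j, d = pairs
    kinds = state.kinds
    n_reactions = 0
    if i.size:
        ch = table.channel_matrix[kinds[i].astype(np.int64),
                                  kinds[j].astype(np.int64)]
        has = ch >= 0
        i, j, d, ch = i[has], j[has], d[has], ch[has]
    else:
        ch = np.empty(0, dtype=np.int64)
    new_pos: list[np.ndarray] = []
    new_kinds: list[int] = []
    if i.size:
        radii = table.radius_matrix[kinds[i].astype(np.int64),
                                    kinds[j].astype(np.int64)]
        due = d <= radii
        box = np.array(state.roi.box_nm)
        order = np.argsort(d[due], kind="stable")
        di, dj, dch = i[due], j[due], ch[due]
        for idx in order:
            a, b = int(di[idx]), int(dj[idx])
            if not (state.alive[a] and state.alive[b]):
                continue
            state.alive[a] = False
            state.alive[b] = False
            n_reactions += 1
            delta = minimum_image(state.positions_nm[b] - state.positions_nm[a],
                                  box)
            mid = np.mod(state.positions_nm[a] + 0.5 * delta, box)
            c = int(dch[idx])
            for p in table.products[c]:
                new_pos.append(mid)
                new_kinds.append(int(p))
            if reaction_log is not None:
                reaction_log.append((state.clock_ps, c,
                                     float(mid[0]), float(mid[1]),
                                     float(mid[2])))
        survive = state.alive[i] & state.alive[j]
        gaps = d[survive] - radii[survive]
        gap = float(gaps.min()) if gaps.size else math.inf
    else:
        gap = math.inf
    if n_reactions:
        state.compact()
        if new_kinds:
            state.positions_nm = np.concatenate(
                [state.positions_nm, np.asarray(new_pos)])
            state.kinds = np.concatenate(
                [state.kinds, np.asarray(new_kinds, dtype=np.int8)])
            state.alive = np.ones(state.kinds.size, dtype=bool)
    return n_reactions, gap


#: Default adaptive step ladder [ps].
DEFAULT_DT_LADDER = (0.1, 1.0, 3.0, 10.0, 100.0, 1000.0)


def choose_dt(gap_nm: float, d_max_nm2_ps: float,
              ladder=DEFAULT_DT_LADDER, dt_min_ps: float = 0.1,
              dt_max_ps: float = 1000.0) -> float:
    """Largest ladder rung whose RMS 3-D displacement fits inside gap/2."""
    if dt_min_ps > dt_max_ps:
        raise ValueError("dt_min_ps must be <= dt_max_ps")
    if not math.isfinite(gap_nm):
        return dt_max_ps
    rungs = [r for r in ladder if dt_min_ps <= r <= dt_max_ps]
    if not rungs:
        rungs = [dt_min_ps]
    if d_max_nm2_ps <= 0:
        return dt_max_ps
    allowed = [r for r in rungs
               if math.sqrt(6.0 * d_max_nm2_ps * r) <= max(gap_nm, 0.0) / 2.0]
    return max(allowed) if allowed else min(rungs)


def measure_gap(state: ChemicalState, table: ReactionTable,
                r_query_nm: float, mode: str = "tree") -> float:
    """Minimum (distance - encounter radius) over reactive pairs in range."""
    i, j, d = find_pairs(state, r_query_nm, mode=mode)
    if i.size == 0:
        return math.inf
    kinds = state.kinds
    ch = table.channel_matrix[kinds[i].astype(np.int64),
                              kinds[j].astype(np.int64)]
    has = ch >= 0
    if not has.any():
        return math.inf
    radii = table.radius_matrix[kinds[i[has]].astype(np.int64),
                                kinds[j[has]].astype(np.int64)]
    return float((d[has] - radii).min())


def adaptive_dt(state: ChemicalState, table: ReactionTable,
                diffusion: DiffusionCoefficients,
                dt_min_ps: float = 0.1, dt_max_ps: float = 1000.0,
                ladder=DEFAULT_DT_LADDER, mode: str = "tree") -> float:
    """Adaptive step for the current configuration (empty state -> dt_max)."""
    if dt_min_ps > dt_max_ps:
        raise ValueError("dt_min_ps must be <= dt_max_ps")
    if state.n_particles == 0:
        return dt_max_ps
    d_arr = diffusion.as_array_nm2_ps()
    present = state.counts() > 0
    d_max = float(d_arr[present].max()) if present.any() else 0.0
    r_query = table.max_radius_nm + 2.0 * math.sqrt(
        6.0 * max(d_max, 1e-30) * dt_max_ps)
    gap = measure_gap(state, table, r_query, mode=mode)
    return choose_dt(gap, d_max, ladder, dt_min_ps, dt_max_ps)


def inject(state: ChemicalState, batch: InitialRadicalBatch) -> ChemicalState:
    """Merge a 1 ps radical batch into the state.

    The batch must not lie in the past; within ``evolve`` the clock is
    advanced to the arrival time by normal stepping before merging, and
    the merged radicals first react on the following step.
    """
    if batch.creation_time_ps < state.clock_ps - 1e-9:
        raise ValueError(
            f"batch at t={batch.creation_time_ps} ps is in the past "
            f"(clock {state.clock_ps} ps)")
    state.compact()
    state.clock_ps = max(state.clock_ps, batch.creation_time_ps)
    if len(batch):
        state.positions_nm = np.concatenate(
            [state.positions_nm, np.asarray(batch.positions_nm, dtype=float)])
        state.kinds = np.concatenate(
            [state.kinds, np.asarray(batch.kinds, dtype=np.int8)])
        state.alive = np.ones(state.kinds.size, dtype=bool)
    state.cumulative_deposited_energy_ev += batch.deposited_energy_ev
    return state


# ---------------------------------------------------------------------------
# Evolution loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepperSettings:
    """Adaptive-stepper controls.

    The ladder and bounds trade accuracy for speed: the smallest rung
    resolves sub-encounter-radius motion, the largest bounds the free
    flight of dilute configurations.  ``engine='auto'`` uses the
    compiled cell-list kernel when numba is available, ``'reference'``
    forces the plain numpy/KD-tree path; both implement the same
    stepping and reaction semantics.  ``skin_nm`` is the Verlet-list
    margin of the compiled kernel.
    """

    ladder_ps: tuple[float, ...] = DEFAULT_DT_LADDER
    dt_min_ps: float = 0.1
    dt_max_ps: float = 1000.0
    record_every_ps: float = 2.0
    neighbor_mode: str = "tree"
    engine: str = "auto"
    skin_nm: float = 12.0


@dataclass
class StepHistory:
    """Piecewise-constant count/energy history emitted by ``evolve``.

    Species counts only change at reactions and injections, so sampling
    this history onto any recording grid is exact.
    """

    times_ps: np.ndarray
    counts: np.ndarray  # (n_snapshots, N_SPECIES)
    energy_ev: np.ndarray

    def sample(self, grid_ps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(self.times_ps, np.asarray(grid_ps) * (1 + 1e-12),
                              side="right") - 1
        idx = np.clip(idx, 0, len(self.times_ps) - 1)
        return self.counts[idx], self.energy_ev[idx]


def evolve(state: ChemicalState, injections: list[InitialRadicalBatch],
           t_end_ps: float, diffusion: DiffusionCoefficients | None = None,
           table: ReactionTable | None = None,
           stepper: StepperSettings | None = None,
           rng: np.random.Generator | int = 0,
           reaction_log: list | None = None) -> StepHistory:
    """Run the SBS loop (adaptive dt -> diffuse -> react) to ``t_end_ps``.

    ``injections`` must be sorted by creation time; steps are clamped so
    the clock lands exactly on every injection time, where chemistry is
    paused and the batch merged.  Returns the piecewise-constant count
    history; the final clock equals ``t_end_ps``.
    """
    diffusion = diffusion or DiffusionCoefficients()
    table = table or ReactionTable.default(diffusion)
    stepper = stepper or StepperSettings()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    times = [b.creation_time_ps for b in injections]
    if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
        raise ValueError("injections must be sorted by creation time")
    if times and t_end_ps < times[-1]:
        raise ValueError("t_end_ps must not precede the last injection")
    from . import _fast
    if (stepper.engine == "auto" and _fast.HAVE_NUMBA
            and stepper.neighbor_mode == "tree"):
        return _evolve_fast(state, injections, t_end_ps, diffusion, table,
                            stepper, rng, reaction_log)

    eps = 1e-9
    d_arr = diffusion.as_array_nm2_ps()
    hist_t = [state.clock_ps]
    hist_counts = [state.counts()]
    hist_e = [state.cumulative_deposited_energy_ev]

    def snapshot() -> None:
        hist_t.append(state.clock_ps)
        hist_counts.append(state.counts())
        hist_e.append(state.cumulative_deposited_energy_ev)

    inj_idx = 0
    gap: float | None = None  # None = stale, recompute from positions
    while True:
        while inj_idx < len(injections) and \
                injections[inj_idx].creation_time_ps <= state.clock_ps + eps:
            inject(state, injections[inj_idx])
            inj_idx += 1
            gap = None
            snapshot()
        if state.clock_ps >= t_end_ps - eps:
            break
        t_next = (injections[inj_idx].creation_time_ps
                  if inj_idx < len(injections) else t_end_ps)
        n_live = state.kinds.size
        if n_live == 0:
            state.clock_ps = t_next
            continue
        present = state.counts() > 0
        d_max = float(d_arr[present].max()) if present.any() else 0.0
        r_query = table.max_radius_nm + 2.0 * math.sqrt(
            6.0 * max(d_max, 1e-30) * stepper.dt_max_ps)
        if gap is None:
            gap = measure_gap(state, table, r_query,
                              mode=stepper.neighbor_mode)
        dt = choose_dt(gap, d_max, stepper.ladder_ps,
                       stepper.dt_min_ps, stepper.dt_max_ps)
        if state.clock_ps + dt >= t_next - eps:
            dt = t_next - state.clock_ps
            state.clock_ps = t_next
        else:
            state.clock_ps = state.clock_ps + dt
        diffuse(state, dt, diffusion, state.roi, rng)
        pairs = find_pairs(state, r_query, mode=stepper.neighbor_mode)
        n_rx, gap = react(state, table, pairs=pairs,
                          reaction_log=reaction_log)
        if n_rx:
            snapshot()
    state.clock_ps = t_end_ps
    snapshot()
    return StepHistory(times_ps=np.asarray(hist_t),
                       counts=np.asarray(hist_counts),
                       energy_ev=np.asarray(hist_e))


def _evolve_fast(state: ChemicalState, injections: list[InitialRadicalBatch],
                 t_end_ps: float, diffusion: DiffusionCoefficients,
                 table: ReactionTable, stepper: StepperSettings,
                 rng: np.random.Generator,
                 reaction_log: list | None) -> StepHistory:
    """Compiled-kernel evolution: same semantics as the reference loop."""
    from . import _fast

    state.compact()
    eps = 1e-9
    n0 = state.kinds.size
    expected = n0 + sum(len(b) for b in injections)
    cap = max(256, 2 * expected + 1024)
    pos = np.zeros((cap, 3))
    kinds = np.full(cap, -1, dtype=np.int64)
    pos[:n0] = state.positions_nm
    kinds[:n0] = state.kinds
    ref = np.zeros((cap, 3))

    counts = state.counts().astype(np.int64)
    state_f = np.array([state.clock_ps,
                        state.cumulative_deposited_energy_ev, -1.0])
    state_i = np.array([n0, 0, 0, 0, 0, 1], dtype=np.int64)

    d_ps = diffusion.as_array_nm2_ps()
    ladder = np.asarray(stepper.ladder_ps, dtype=float)
    prod_off = np.zeros(len(table.products) + 1, dtype=np.int64)
    for c, prods in enumerate(table.products):
        prod_off[c + 1] = prod_off[c] + prods.size
    prod_flat = (np.concatenate(table.products)
                 if table.products else np.empty(0, dtype=np.int8)
                 ).astype(np.int64)

    snap_cap = 4096
    snap_t = np.zeros(snap_cap)
    snap_counts = np.zeros((snap_cap, N_SPECIES), dtype=np.int64)
    snap_e = np.zeros(snap_cap)
    pair_cap = max(4096, 64 * max(n0, 1))
    pair_i = np.zeros(pair_cap, dtype=np.int64)
    pair_j = np.zeros(pair_cap, dtype=np.int64)
    log_on = 1 if reaction_log is not None else 0
    log_cap = max(1024, 4 * expected) if log_on else 1
    log_t = np.zeros(log_cap)
    log_ch = np.zeros(log_cap, dtype=np.int64)
    log_xyz = np.zeros((log_cap, 3))

    def draw_normals() -> np.ndarray:
        n_slots = int(state_i[0])
        chunk = int(min(6.0e6, max(1.0e5, 600.0 * max(n_slots, 1))))
        state_i[1] = 0
        return rng.standard_normal(chunk)

    normals = draw_normals()

    hist_t = [state.clock_ps]
    hist_counts = [counts.copy()]
    hist_e = [state_f[1]]

    def grow_particles() -> None:
        nonlocal pos, kinds, ref, cap
        cap *= 2
        pos2 = np.zeros((cap, 3)); pos2[:pos.shape[0]] = pos
        kinds2 = np.full(cap, -1, dtype=np.int64)
        kinds2[:kinds.shape[0]] = kinds
        ref2 = np.zeros((cap, 3)); ref2[:ref.shape[0]] = ref
        pos, kinds, ref = pos2, kinds2, ref2

    def merge(batch: InitialRadicalBatch) -> None:
        nonlocal pos, kinds, ref
        m = len(batch)
        while int(state_i[0]) + m > cap:
            grow_particles()
        n = int(state_i[0])
        if m:
            pos[n:n + m] = batch.positions_nm
            kinds[n:n + m] = np.asarray(batch.kinds, dtype=np.int64)
            state_i[0] = n + m
            for k in np.asarray(batch.kinds, dtype=np.int64):
                counts[k] += 1
        state_f[1] += batch.deposited_energy_ev
        state_i[5] = 1  # neighbor lists stale
        hist_t.append(state_f[0])
        hist_counts.append(counts.copy())
        hist_e.append(state_f[1])

    inj_idx = 0
    while True:
        while inj_idx < len(injections) and \
                injections[inj_idx].creation_time_ps <= state_f[0] + eps:
            if injections[inj_idx].creation_time_ps < state.clock_ps - eps:
                raise ValueError("injection in the past")
            merge(injections[inj_idx])
            inj_idx += 1
        if state_f[0] >= t_end_ps - eps:
            break
        t_stop = (injections[inj_idx].creation_time_ps
                  if inj_idx < len(injections) else t_end_ps)
        status = _fast.run_segment(
            pos, kinds, state_f, state_i, t_stop, np.asarray(state.roi.box_nm),
            d_ps, table.channel_matrix.astype(np.int64), table.radius_matrix,
            prod_flat, prod_off, ladder, stepper.dt_min_ps, stepper.dt_max_ps,
            table.max_radius_nm, stepper.skin_nm,
            normals, snap_t, snap_counts, snap_e, counts,
            pair_i, pair_j, ref, log_t, log_ch, log_xyz, log_on)
        if status == _fast.NEED_NORMALS:
            normals = draw_normals()
        elif status == _fast.SNAP_FULL:
            hist_t.extend(snap_t[:int(state_i[2])])
            hist_counts.extend(snap_counts[:int(state_i[2])].copy())
            hist_e.extend(snap_e[:int(state_i[2])])
            state_i[2] = 0
        elif status == _fast.PAIRS_FULL:
            pair_cap *= 2
            pair_i = np.zeros(pair_cap, dtype=np.int64)
            pair_j = np.zeros(pair_cap, dtype=np.int64)
            state_i[5] = 1
        elif status == _fast.PARTICLES_FULL:
            grow_particles()
            state_i[5] = 1
        elif status == _fast.LOG_FULL:
            reaction_log.extend(
                (log_t[q], int(log_ch[q]), log_xyz[q, 0], log_xyz[q, 1],
                 log_xyz[q, 2]) for q in range(int(state_i[4])))
            state_i[4] = 0

    ns = int(state_i[2])
    hist_t.extend(snap_t[:ns])
    hist_counts.extend(snap_counts[:ns].copy())
    hist_e.extend(snap_e[:ns])
    if reaction_log is not None:
        reaction_log.extend(
            (log_t[q], int(log_ch[q]), log_xyz[q, 0], log_xyz[q, 1],
             log_xyz[q, 2]) for q in range(int(state_i[4])))

    # write the final configuration back into the caller's state
    n = int(state_i[0])
    live = kinds[:n] >= 0
    state.positions_nm = pos[:n][live].copy()
    state.kinds = kinds[:n][live].astype(np.int8)
    state.alive = np.ones(state.kinds.size, dtype=bool)
    state.clock_ps = t_end_ps
    state.cumulative_deposited_energy_ev = float(state_f[1])

    hist_t.append(t_end_ps)
    hist_counts.append(counts.copy())
    hist_e.append(state_f[1])
    order = np.argsort(np.asarray(hist_t), kind="stable")
    return StepHistory(times_ps=np.asarray(hist_t)[order],
                       counts=np.asarray(hist_counts)[order],
                       energy_ev=np.asarray(hist_e)[order])
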