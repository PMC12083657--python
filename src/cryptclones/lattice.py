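"""On-lattice voter-type simulator of colonic crypt population dynamics.

Each site of an M×M periodic lattice represents one crypt and carries a state
``s ∈ {-1, 0, +1}``: ``-1`` unlabelled (UL), ``0`` empty, ``+1`` labelled (L).
The neighbourhood of a site is the six-member set

    N(i,j) = {(i,j+1),(i,j-1),(i+1,j),(i-1,j),(i+1,j+1),(i-1,j-1)}

(indices wrapped modulo M), the standard embedding of a hexagonal lattice in a
square array. The lattice is a flattened representation of the colonic tube
opened longitudinally, hence periodic boundaries on both axes.

Dynamics: at each time step one site is drawn uniformly at random and updated
under three moves parameterised per state s by a fission probability rho_s, a
fusion probability f_s and a monoclonal-fixation probability P_s:

1. empty site, all neighbours empty: nothing happens;
2. empty site with non-empty neighbours: a non-empty neighbour is drawn
   uniformly and copies its state into the empty site with that neighbour's
   fission probability (a crypt fissions into the gap);
3. non-empty site: a neighbour is drawn uniformly among all six. If it is
   empty, the chosen site fissions into it with its own fission probability.
   If it is non-empty the two crypts fuse with probability (f_a + f_b)/2: one
   of the pair (equal odds) is emptied, and the survivor's state is the
   monoclonal-fixation outcome, state a winning with probability
   P_a / (P_a + P_b) (a fair coin when both fixation probabilities are zero).

Acute damage is modelled by emptying the right half of the lattice (columns
M/2 .. M-1) at a configurable step, after which the tissue regrows from the
intact half — from both sides, because of the periodic (cylindrical) topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit

__all__ = [
    "NEIGHBOUR_OFFSETS",
    "SimParams",
    "LatticeState",
    "SimResult",
    "init_lattice",
    "neighbours",
    "step",
    "apply_damage",
    "run_simulation",
    "run_replicates",
    "detect_homeostasis",
    "repair_time",
]

#: Hexagonal-embedding neighbour offsets (row, column), wrapped modulo M.
NEIGHBOUR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1),
    (0, -1),
    (1, 0),
    (-1, 0),
    (1, 1),
    (-1, -1),
)

_DI = np.array([o[0] for o in NEIGHBOUR_OFFSETS], dtype=np.int64)
_DJ = np.array([o[1] for o in NEIGHBOUR_OFFSETS], dtype=np.int64)

# state -> index used in count arrays
LABELLED, UNLABELLED, EMPTY = 0, 1, 2


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulation scenario.

    Probabilities are unitless and per update attempt; the neutral baseline is
    rho = f = P = 0.5 for both states. The fission-bias scenario raises
    ``fission_labelled`` to 0.95 with everything else unchanged.
    """

    lattice_size: int = 100
    fission_labelled: float = 0.5
    fission_unlabelled: float = 0.5
    fusion_labelled: float = 0.5
    fusion_unlabelled: float = 0.5
    fixation_labelled: float = 0.5
    fixation_unlabelled: float = 0.5
    labelling_efficiency: float = 0.2
    damage_step: Optional[int] = None
    total_steps: int = 100_000
    record_every: int = 100
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        M = self.lattice_size
        if M < 4 or M % 2 != 0:
            raise ValueError(f"lattice_size must be an even integer >= 4, got {M}")
        for name in (
            "fission_labelled",
            "fission_unlabelled",
            "fusion_labelled",
            "fusion_unlabelled",
            "fixation_labelled",
            "fixation_unlabelled",
            "labelling_efficiency",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.total_steps < 1:
            raise ValueError("total_steps must be positive")
        if self.record_every < 1:
            raise ValueError("record_every must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.damage_step is not None and not 0 <= self.damage_step < self.total_steps:
            raise ValueError("damage_step must satisfy 0 <= damage_step < total_steps")

    def fission(self, s: int) -> float:
        return self.fission_labelled if s == 1 else self.fission_unlabelled

    def fusion(self, s: int) -> float:
        return self.fusion_labelled if s == 1 else self.fusion_unlabelled

    def fixation(self, s: int) -> float:
        return self.fixation_labelled if s == 1 else self.fixation_unlabelled

    def _prob_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Probabilities indexed by state+1 (-1 -> 0, 0 -> 1 unused, +1 -> 2)."""
        rho = np.array([self.fission_unlabelled, 0.0, self.fission_labelled])
        fus = np.array([self.fusion_unlabelled, 0.0, self.fusion_labelled])
        fix = np.array([self.fixation_unlabelled, 0.0, self.fixation_labelled])
        return rho, fus, fix


@dataclass
class LatticeState:
    """An M×M grid of crypt states plus the simulation-step counter."""

    grid: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be a square matrix")
        if not np.isin(self.grid, (-1, 0, 1)).all():
            raise ValueError("grid entries must lie in {-1, 0, +1}")

    @property
    def lattice_size(self) -> int:
        return self.grid.shape[0]

    def copy(self) -> "LatticeState":
        return LatticeState(self.grid.copy(), self.step)

    def half_counts(self) -> np.ndarray:
        """(2, 3) array of [labelled, unlabelled, empty] counts per half.

        Half 0 is columns 0..M/2-1 ("left"), half 1 columns M/2..M-1 ("right").
        """
        M = self.lattice_size
        out = np.zeros((2, 3), dtype=np.int64)
        for h, sl in enumerate((slice(0, M // 2), slice(M // 2, M))):
            sub = self.grid[:, sl]
            out[h, LABELLED] = int((sub == 1).sum())
            out[h, UNLABELLED] = int((sub == -1).sum())
            out[h, EMPTY] = int((sub == 0).sum())
        return out


@dataclass
class SimResult:
    """Recorded time series of one simulation replicate.

    ``counts_left``/``counts_right`` hold per recorded step the
    [labelled, unlabelled, empty] counts of each lattice half;
    ``aggregation_left``/``aggregation_right`` the site-aggregation value 1-C
    of each half (NaN where no non-empty neighbour pairs exist).
    """

    params: SimParams
    recorded_steps: np.ndarray
    counts_left: np.ndarray
    counts_right: np.ndarray
    aggregation_left: np.ndarray
    aggregation_right: np.ndarray
    final_state: LatticeState
    repair_steps: Optional[int] = None

    def occupancy_right(self) -> np.ndarray:
        """Non-empty site count of the right (damage-target) half."""
        return self.counts_right[:, LABELLED] + self.counts_right[:, UNLABELLED]


def init_lattice(
    params: SimParams,
    rng: np.random.Generator,
    exact_counts: bool = False,
) -> LatticeState:
    """Initial fully occupied lattice with labelled fraction = labelling efficiency.

    Each site is independently labelled with probability
    ``params.labelling_efficiency`` and unlabelled otherwise (no empty sites).
    With ``exact_counts=True`` exactly ``round(eff * M**2)`` labelled sites are
    placed at uniformly random positions instead of i.i.d. draws.
    """
    M = params.lattice_size
    eff = params.labelling_efficiency
    if exact_counts:
        flat = np.full(M * M, -1, dtype=np.int8)
        n_lab = int(round(eff * M * M))
        idx = rng.choice(M * M, size=n_lab, replace=False)
        flat[idx] = 1
        grid = flat.reshape(M, M)
    else:
        grid = np.where(rng.random((M, M)) < eff, 1, -1).astype(np.int8)
    return LatticeState(grid, step=0)


def neighbours(i: int, j: int, M: int) -> set[tuple[int, int]]:
    """The six hexagonal neighbours of (i, j), wrapped modulo M."""
    if not (0 <= i < M and 0 <= j < M):
        raise IndexError(f"site ({i}, {j}) outside a {M}x{M} lattice")
    return {((i + di) % M, (j + dj) % M) for di, dj in NEIGHBOUR_OFFSETS}


def step(state: LatticeState, params: SimParams, rng: np.random.Generator) -> LatticeState:
    """One update attempt: the readable reference implementation.

    Returns a new state with ``step`` incremented; at most two sites change.
    (`run_simulation` uses a compiled kernel implementing the same rules.)
    """
    M = state.lattice_size
    grid = state.grid.copy()
    i = int(rng.integers(M))
    j = int(rng.integers(M))
    s = int(grid[i, j])
    nbrs = [((i + di) % M, (j + dj) % M) for di, dj in NEIGHBOUR_OFFSETS]
    if s == 0:
        non_empty = [(k, l) for k, l in nbrs if grid[k, l] != 0]
        if non_empty:
            k, l = non_empty[int(rng.integers(len(non_empty)))]
            sn = int(grid[k, l])
            if rng.random() < params.fission(sn):
                grid[i, j] = sn
    else:
        k, l = nbrs[int(rng.integers(6))]
        sn = int(grid[k, l])
        if sn == 0:
            if rng.random() < params.fission(s):
                grid[k, l] = s
        else:
            if rng.random() < 0.5 * (params.fusion(s) + params.fusion(sn)):
                # fusion: one of the pair is emptied, the other takes the
                # monoclonal-fixation outcome
                emptied_first = rng.random() < 0.5
                (ei, ej), (pi, pj) = ((i, j), (k, l)) if emptied_first else ((k, l), (i, j))
                tot = params.fixation(s) + params.fixation(sn)
                p_a = 0.5 if tot == 0.0 else params.fixation(s) / tot
                s_prime = s if rng.random() < p_a else sn
                grid[ei, ej] = 0
                grid[pi, pj] = s_prime
    return LatticeState(grid, state.step + 1)


def apply_damage(state: LatticeState) -> LatticeState:
    """Empty the right half of the lattice (columns M/2 .. M-1). Idempotent."""
    M = state.lattice_size
    grid = state.grid.copy()
    grid[:, M // 2 :] = 0
    return LatticeState(grid, state.step)


@njit(cache=True)
def _agg_half(grid, col_lo, col_hi, di, dj):  # pragma: no cover - compiled
    """(alpha, beta) ordered-link counts with the focal site in [col_lo, col_hi)."""
    M = grid.shape[0]
    alpha = 0
    beta = 0
    for i in range(M):
        for j in range(col_lo, col_hi):
            s = grid[i, j]
            if s == 0:
                continue
            for n in range(6):
                t = grid[(i + di[n]) % M, (j + dj[n]) % M]
                if t == 0:
                    continue
                beta += 1
                if t != s:
                    alpha += 1
    return alpha, beta


@njit(cache=True)
def _simulate_core(  # pragma: no cover - compiled
    M,
    rho,
    fus,
    fix,
    eff,
    total_steps,
    damage_step,
    record_every,
    seed,
    di,
    dj,
):
    np.random.seed(seed)
    grid = np.empty((M, M), dtype=np.int8)
    for i in range(M):
        for j in range(M):
            grid[i, j] = 1 if np.random.random() < eff else -1

    half = M // 2
    live = np.zeros((2, 3), dtype=np.int64)  # [half, (L, UL, empty)]
    for i in range(M):
        for j in range(M):
            h = 0 if j < half else 1
            s = grid[i, j]
            if s == 1:
                live[h, 0] += 1
            elif s == -1:
                live[h, 1] += 1
            else:
                live[h, 2] += 1

    n_rec = total_steps // record_every + 1
    rec_steps = np.empty(n_rec, dtype=np.int64)
    counts = np.zeros((n_rec, 2, 3), dtype=np.int64)
    agg = np.full((n_rec, 2), np.nan)

    rec_steps[0] = 0
    counts[0] = live
    for h in range(2):
        a, b = _agg_half(grid, h * half, (h + 1) * half, di, dj)
        if b > 0:
            agg[0, h] = 1.0 - a / b

    nk = np.empty(6, dtype=np.int64)
    nl = np.empty(6, dtype=np.int64)
    r = 0
    for t in range(1, total_steps + 1):
        if damage_step >= 0 and t - 1 == damage_step:
            # acute damage: empty the right half
            for i in range(M):
                for j in range(half, M):
                    s = grid[i, j]
                    if s == 1:
                        live[1, 0] -= 1
                        live[1, 2] += 1
                    elif s == -1:
                        live[1, 1] -= 1
                        live[1, 2] += 1
                    grid[i, j] = 0

        i = np.random.randint(0, M)
        j = np.random.randint(0, M)
        s = grid[i, j]
        if s == 0:
            cnt = 0
            for n in range(6):
                k = (i + di[n]) % M
                l = (j + dj[n]) % M
                if grid[k, l] != 0:
                    nk[cnt] = k
                    nl[cnt] = l
                    cnt += 1
            if cnt > 0:
                c = np.random.randint(0, cnt)
                k = nk[c]
                l = nl[c]
                sn = grid[k, l]
                if np.random.random() < rho[sn + 1]:
                    grid[i, j] = sn
                    h = 0 if j < half else 1
                    live[h, 2] -= 1
                    live[h, 0 if sn == 1 else 1] += 1
        else:
            n = np.random.randint(0, 6)
            k = (i + di[n]) % M
            l = (j + dj[n]) % M
            sn = grid[k, l]
            if sn == 0:
                if np.random.random() < rho[s + 1]:
                    grid[k, l] = s
                    h = 0 if l < half else 1
                    live[h, 2] -= 1
                    live[h, 0 if s == 1 else 1] += 1
            else:
                if np.random.random() < 0.5 * (fus[s + 1] + fus[sn + 1]):
                    if np.random.random() < 0.5:
                        ei, ej, pi, pj = i, j, k, l
                    else:
                        ei, ej, pi, pj = k, l, i, j
                    tot = fix[s + 1] + fix[sn + 1]
                    p_a = 0.5 if tot == 0.0 else fix[s + 1] / tot
                    s_prime = s if np.random.random() < p_a else sn
                    se = grid[ei, ej]
                    he = 0 if ej < half else 1
                    live[he, 0 if se == 1 else 1] -= 1
                    live[he, 2] += 1
                    grid[ei, ej] = 0
                    sp = grid[pi, pj]
                    if sp != s_prime:
                        hp = 0 if pj < half else 1
                        live[hp, 0 if sp == 1 else 1] -= 1
                        live[hp, 0 if s_prime == 1 else 1] += 1
                        grid[pi, pj] = s_prime

        if t % record_every == 0:
            r += 1
            rec_steps[r] = t
            counts[r] = live
            for h in range(2):
                a, b = _agg_half(grid, h * half, (h + 1) * half, di, dj)
                if b > 0:
                    agg[r, h] = 1.0 - a / b

    return grid, rec_steps, counts, agg


def _replicate_seed(master_seed: int, replicate: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_simulation(
    params: SimParams,
    replicate: int = 0,
    recovery_rel_tol: float = 0.05,
) -> SimResult:
    """Run one replicate and return its recorded series.

    The kernel records per-half counts and aggregation every
    ``params.record_every`` steps (including step 0). When a ``damage_step``
    is set, ``repair_steps`` holds the time from damage until the right-half
    occupancy first re-enters ``recovery_rel_tol`` of its pre-damage plateau.
    """
    rho, fus, fix = params._prob_arrays()
    damage = -1 if params.damage_step is None else int(params.damage_step)
    grid, rec_steps, counts, agg = _simulate_core(
        params.lattice_size,
        rho,
        fus,
        fix,
        params.labelling_efficiency,
        params.total_steps,
        damage,
        params.record_every,
        _replicate_seed(params.seed, replicate),
        _DI,
        _DJ,
    )
    result = SimResult(
        params=params,
        recorded_steps=rec_steps,
        counts_left=counts[:, 0, :],
        counts_right=counts[:, 1, :],
        aggregation_left=agg[:, 0],
        aggregation_right=agg[:, 1],
        final_state=LatticeState(grid, int(rec_steps[-1])),
    )
    if params.damage_step is not None:
        result.repair_steps = repair_time(result, rel_tol=recovery_rel_tol)
    return result


def run_replicates(params: SimParams, recovery_rel_tol: float = 0.05) -> list[SimResult]:
    """Run ``params.n_replicates`` independent replicates (seeds derived from params.seed)."""
    return [
        run_simulation(params, replicate=r, recovery_rel_tol=recovery_rel_tol)
        for r in range(params.n_replicates)
    ]


def detect_homeostasis(
    empty_series: Sequence[float],
    window: int = 2000,
    rel_tol: float = 0.01,
    steps: Optional[Sequence[int]] = None,
) -> Optional[int]:
    """First recorded step at which the empty-site count has plateaued.

    Compares the mean of each length-``window`` block of the recorded series
    with the mean of the preceding block; the plateau is declared at the end
    of the first block whose mean changed by less than ``rel_tol`` relative to
    the previous block (absolute change below ``rel_tol`` when the previous
    mean is zero). Returns None if no plateau is found.
    """
    series = np.asarray(empty_series, dtype=float)
    if series.size == 0:
        raise ValueError("empty_series must be non-empty")
    if window < 1 or 2 * window > series.size:
        raise ValueError("window must satisfy 1 <= 2*window <= len(series)")
    for end in range(2 * window, series.size + 1):
        prev = series[end - 2 * window : end - window].mean()
        cur = series[end - window : end].mean()
        change = abs(cur - prev) if prev == 0 else abs(cur - prev) / abs(prev)
        if change < rel_tol:
            idx = end - 1
            return int(steps[idx]) if steps is not None else idx
    return None


def _pre_damage_plateau(result: SimResult) -> tuple[float, int]:
    """Mean right-half occupancy over the recorded quarter preceding damage."""
    damage = result.params.damage_step
    if damage is None:
        raise ValueError("simulation was run without damage")
    rec = result.recorded_steps
    pre = np.nonzero(rec <= damage)[0]
    if pre.size == 0:
        raise ValueError("no recorded step precedes the damage step")
    lo = pre[max(0, pre.size - max(1, pre.size // 4)) :]
    occ = result.occupancy_right()
    return float(occ[lo].mean()), int(pre[-1])


def repair_time(result: SimResult, rel_tol: float = 0.05) -> Optional[int]:
    """Steps from damage until right-half occupancy re-enters ``rel_tol`` of its plateau.

    The plateau is the mean right-half occupancy over the last quarter of
    recorded points before damage. Returns None when the run ends before
    recovery.
    """
    plateau, last_pre = _pre_damage_plateau(result)
    occ = result.occupancy_right()
    target = (1.0 - rel_tol) * plateau
    post = np.nonzero(
        (result.recorded_steps > result.params.damage_step) & (occ >= target)
    )[0]
    if post.size == 0:
        return None
    return int(result.recorded_steps[post[0]] - result.params.damage_step)


def mean_counts(results: Sequence[SimResult]) -> dict[str, np.ndarray]:
    """Replicate-averaged recorded series (common recording grid required)."""
    rec = results[0].recorded_steps
    for r in results[1:]:
        if not np.array_equal(r.recorded_steps, rec):
            raise ValueError("replicates were recorded on different step grids")
    return {
        "recorded_steps": rec,
        "counts_left": np.mean([r.counts_left for r in results], axis=0),
        "counts_right": np.mean([r.counts_right for r in results], axis=0),
        "aggregation_left": np.nanmean([r.aggregation_left for r in results], axis=0),
        "aggregation_right": np.nanmean([r.aggregation_right for r in results], axis=0),
    }
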