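"""Three-stage combinatorial FDI assignment for detected teeth.

The N detected teeth of a scan are mapped to the C = 32 FDI codes through a
binary assignment matrix E (N x 32, row sums <= 1).  The exact minimization
over all assignments is intractable at scan scale, so the assignment is
refined in three stages, each searching a neighborhood of the previous one:

1. *Greedy* — minimize ``f1 = f11 + lambda12*f12 + lambda13*f13`` where f11
   penalizes an FDI code given to more than one detection, f12 an assignment
   to the wrong half jaw (judged against the watershed: the z component of
   the scan-wide mean COM), and f13 every unassigned detection.  Default
   weights: lambda12 = 0.1, lambda13 = 0.01.
2. *Permutation sort* — within each jaw, keep the set of assigned detections
   and the multiset of used codes but permute which detection gets which
   code, minimizing the inversion count f2 between left-right (x) order of
   COMs and code order along the arch.  Sorting achieves the global minimum.
3. *Slot refinement* — keep the sorted order but allow blank slots (missing
   teeth): enumerate every order-preserving placement of the jaw's detection
   sequence into the 16 arch slots and pick the one minimizing f3, the
   discrepancy between observed pairwise COM distances and a distance prior
   D (mean inter-tooth distance in mm, estimated from labeled scans).

Code order along the arch uses the *arch index* (see :mod:`archlabel.fdi`):
raw FDI numerals reverse direction at the midline, so comparing them directly
would break the intended monotonicity; a config flag restores the raw-numeral
comparison for fidelity experiments.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import fdi
from .errors import PriorMissingError
from .geometry import ArchScene

C = 32


@dataclass(frozen=True)
class PenaltyWeights:
    """Weights of the jaw (f12) and unassigned (f13) terms inside f1."""

    lambda12: float = 0.1
    lambda13: float = 0.01

    def __post_init__(self):
        if self.lambda12 < 0 or self.lambda13 < 0:
            raise ValueError("penalty weights must be non-negative")


@dataclass(frozen=True)
class LabelingConfig:
    """Switches for the documented design choices.

    order_by_arch_index
        Compare codes by arch index (default) or by raw FDI numeral in
        f2/stage 2.
    f3_metric
        'squared' (default) or 'abs' discrepancy between observed distance
        and prior.
    upper_above_watershed
        Upper-jaw teeth are expected at COM_z >= watershed; set False for
        scans with an inverted z axis.
    """

    order_by_arch_index: bool = True
    f3_metric: str = "squared"
    upper_above_watershed: bool = True

    def __post_init__(self):
        if self.f3_metric not in ("squared", "abs"):
            raise ValueError("f3_metric must be 'squared' or 'abs'")


DEFAULT_CONFIG = LabelingConfig()


@dataclass
class DistancePrior:
    """32x32 matrix of mean inter-tooth COM distances in mm.

    ``d[i, j]`` is the mean Euclidean distance between the COMs of the teeth
    with FDI codes ``fdi.FDI_CODES[i]`` and ``[j]``; NaN flags an entry with
    no observation behind it (cross-jaw entries are never used and stay NaN).
    ``support`` counts the observations behind each mean.
    """

    d: np.ndarray
    support: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, float)
        self.support = np.asarray(self.support, int)
        if self.d.shape != (C, C) or self.support.shape != (C, C):
            raise ValueError("prior matrices must be 32x32")

    def distance(self, code1: int, code2: int) -> float:
        return float(self.d[fdi.CODE_TO_COLUMN[code1], fdi.CODE_TO_COLUMN[code2]])

    def is_missing(self, code1: int, code2: int) -> bool:
        return bool(np.isnan(self.distance(code1, code2)))

    def jaw_submatrix(self, jaw: str) -> np.ndarray:
        """16x16 distances between the jaw's codes in arch order."""
        cols = fdi.JAW_COLUMNS[jaw]
        return self.d[np.ix_(cols, cols)]

    def to_csv(self, path) -> None:
        import pandas as pd

        frame = pd.DataFrame(self.d, index=fdi.FDI_CODES, columns=fdi.FDI_CODES)
        frame.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistancePrior":
        import pandas as pd

        frame = pd.read_csv(path, index_col=0)
        frame.index = frame.index.astype(int)
        frame.columns = frame.columns.astype(int)
        if list(frame.index) != list(fdi.FDI_CODES) or list(frame.columns) != list(
            fdi.FDI_CODES
        ):
            raise PriorMissingError(
                "prior CSV must carry the 32 FDI codes as header row and column"
            )
        d = frame.to_numpy(float)
        support = (~np.isnan(d)).astype(int)
        np.fill_diagonal(support, 0)
        return cls(d=d, support=support)


# --- assignment-matrix helpers ----------------------------------------------

def empty_assignment(n: int) -> np.ndarray:
    return np.zeros((n, C), dtype=np.int8)


def validate_assignment(E: np.ndarray) -> np.ndarray:
    E = np.asarray(E)
    if E.ndim != 2 or E.shape[1] != C:
        raise ValueError("assignment matrix must be N x 32")
    if not np.isin(E, (0, 1)).all():
        raise ValueError("assignment entries must be binary")
    if (E.sum(axis=1) > 1).any():
        raise ValueError("each detection may carry at most one FDI code")
    return E.astype(np.int8)


def assignment_codes(E: np.ndarray) -> list[int | None]:
    """Per-row FDI code, None for unassigned rows."""
    out: list[int | None] = [None] * len(E)
    rows, cols = np.nonzero(E)
    for r, c in zip(rows.tolist(), cols.tolist()):
        out[r] = fdi.FDI_CODES[c]
    return out


def _detection_jaws(scene: ArchScene, config: LabelingConfig) -> np.ndarray:
    """Jaw of each detection: the jaw_hint when single-jaw, else watershed side."""
    if scene.jaw_hint in (fdi.UPPER, fdi.LOWER):
        return np.array([scene.jaw_hint] * len(scene))
    above = scene.coms()[:, 2] >= scene.watershed_z
    if not config.upper_above_watershed:
        above = ~above
    return np.where(above, fdi.UPPER, fdi.LOWER)


# --- penalty terms -----------------------------------------------------------

def penalty_f11(E: np.ndarray) -> float:
    """Count of duplicate uses of each FDI code: sum_c max(sum_n e_nc - 1, 0)."""
    return float(np.maximum(E.sum(axis=0) - 1, 0).sum())


def penalty_f12(
    E: np.ndarray,
    coms: np.ndarray,
    watershed_z: float,
    jaws: np.ndarray | None = None,
    upper_above_watershed: bool = True,
) -> float:
    """Count of assignments on the wrong side of the jaw watershed.

    The literal rule counts upper-jaw assignments with COM_z strictly below
    the watershed plus lower-jaw assignments strictly above it.  When
    ``jaws`` is given (single-jaw scans), it overrides the watershed test.
    """
    coms = np.atleast_2d(np.asarray(coms, float))
    if jaws is not None:
        upper_wrong = jaws == fdi.LOWER
        lower_wrong = jaws == fdi.UPPER
    else:
        z = coms[:, 2]
        if upper_above_watershed:
            upper_wrong = z < watershed_z
            lower_wrong = z > watershed_z
        else:
            upper_wrong = z > watershed_z
            lower_wrong = z < watershed_z
    upper_assigned = E[:, fdi.JAW_COLUMNS[fdi.UPPER]].sum(axis=1)
    lower_assigned = E[:, fdi.JAW_COLUMNS[fdi.LOWER]].sum(axis=1)
    return float((upper_assigned * upper_wrong).sum() + (lower_assigned * lower_wrong).sum())


def penalty_f13(E: np.ndarray) -> float:
    """Count of unassigned detections: sum_n max(1 - sum_c e_nc, 0)."""
    return float(np.maximum(1 - E.sum(axis=1), 0).sum())


def penalty_f1(
    E: np.ndarray,
    coms: np.ndarray,
    watershed_z: float,
    weights: PenaltyWeights = PenaltyWeights(),
    jaws: np.ndarray | None = None,
    upper_above_watershed: bool = True,
) -> float:
    """f1 = f11 + lambda12*f12 + lambda13*f13."""
    return (
        penalty_f11(E)
        + weights.lambda12
        * penalty_f12(E, coms, watershed_z, jaws, upper_above_watershed)
        + weights.lambda13 * penalty_f13(E)
    )


def _jaw_assignments(E: np.ndarray, jaw: str) -> tuple[np.ndarray, np.ndarray]:
    """(rows, arch indices) of the assignments within one jaw."""
    rows, local = np.nonzero(E[:, fdi.JAW_COLUMNS[jaw]])
    return rows, local


def penalty_f2(
    E: np.ndarray, coms: np.ndarray, order_by_arch_index: bool = True
) -> float:
    """Inversion count between x order of COMs and code order along the arch.

    Evaluates the double sum over ordered same-jaw pairs of the exclusive-or
    indicator ``(x1 > x2) XOR (c1 > c2)``; each unordered inversion therefore
    contributes 2.
    """
    coms = np.atleast_2d(np.asarray(coms, float))
    total = 0
    for jaw in (fdi.UPPER, fdi.LOWER):
        rows, local = _jaw_assignments(E, jaw)
        if len(rows) < 2:
            continue
        if order_by_arch_index:
            keys = local
        else:
            keys = np.array([fdi.ARCH_ORDER[jaw][a] for a in local])
        x = coms[rows, 0]
        x_greater = x[:, None] > x[None, :]
        key_greater = keys[:, None] > keys[None, :]
        total += int(np.sum(x_greater ^ key_greater))
    return float(total)


def _discrepancy(delta: np.ndarray, metric: str) -> np.ndarray:
    return delta**2 if metric == "squared" else np.abs(delta)


def penalty_f3(
    E: np.ndarray,
    coms: np.ndarray,
    prior: DistancePrior,
    metric: str = "squared",
    strict: bool = False,
) -> float:
    """Distance-prior discrepancy over ordered same-jaw assigned pairs.

    Each pair contributes ``(|COM_1 - COM_2| - D_{c1 c2})^2`` (or the
    absolute difference under ``metric='abs'``).  Pairs whose prior entry is
    missing are skipped with a warning, or raise when ``strict``.
    """
    coms = np.atleast_2d(np.asarray(coms, float))
    total = 0.0
    for jaw in (fdi.UPPER, fdi.LOWER):
        rows, local = _jaw_assignments(E, jaw)
        k = len(rows)
        if k < 2:
            continue
        pts = coms[rows]
        dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        dsub = prior.jaw_submatrix(jaw)[np.ix_(local, local)]
        missing = np.isnan(dsub)
        np.fill_diagonal(missing, False)
        if missing.any():
            pairs = sorted(
                {
                    tuple(
                        sorted(
                            (fdi.ARCH_ORDER[jaw][local[i]], fdi.ARCH_ORDER[jaw][local[j]])
                        )
                    )
                    for i, j in zip(*np.nonzero(missing))
                }
            )
            if strict:
                raise PriorMissingError(f"no prior distance for code pairs {pairs}")
            warnings.warn(
                f"skipping {len(pairs)} code pairs with missing prior entries: {pairs}",
                stacklevel=2,
            )
        term = _discrepancy(dist - dsub, metric)
        term[missing] = 0.0
        np.fill_diagonal(term, 0.0)
        total += float(term.sum())
    return total


# --- stage 1: greedy ---------------------------------------------------------

def stage1_greedy(
    scene: ArchScene,
    weights: PenaltyWeights = PenaltyWeights(),
    config: LabelingConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Greedy f1 minimization.

    Detections are visited in increasing COM_x; each receives the code with
    the lowest incremental f1 (free codes of its own jaw first, lowest arch
    index on ties) or stays unassigned when every assignment would raise f1.
    """
    if len(scene) == 0:
        raise ValueError("cannot label an empty scene")
    jaws = _detection_jaws(scene, config)
    coms = scene.coms()
    E = empty_assignment(len(scene))
    taken = np.zeros(C, bool)
    order = sorted(range(len(scene)), key=lambda i: (coms[i, 0], i))
    for i in order:
        candidates = [
            (
                (1.0 if taken[col] else 0.0)
                + weights.lambda12 * (fdi.JAW_OF_COLUMN[col] != jaws[i])
                - weights.lambda13,
                fdi.JAW_OF_COLUMN[col] != jaws[i],
                int(fdi.ARCH_INDEX_OF_COLUMN[col]),
                col,
            )
            for col in range(C)
        ]
        delta, _, _, col = min(candidates)
        if delta <= 0:
            E[i, col] = 1
            taken[col] = True
    return E


# --- stage 2: permutation sort ----------------------------------------------

def stage2_sort(
    E1: np.ndarray, scene: ArchScene, config: LabelingConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Permute each jaw's used codes so code order follows COM_x order.

    Keeps, per jaw, both the set of assigned detections and the multiset of
    used codes; sorting attains the global minimum of the inversion count f2
    (zero whenever the x coordinates are distinct).  Ties in x are broken by
    detection index, duplicate codes keep their multiplicity.
    """
    E1 = validate_assignment(E1)
    coms = scene.coms()
    E2 = empty_assignment(len(E1))
    for jaw in (fdi.UPPER, fdi.LOWER):
        rows, local = _jaw_assignments(E1, jaw)
        if len(rows) == 0:
            continue
        if config.order_by_arch_index:
            code_order = sorted(local.tolist())
        else:
            code_order = sorted(
                local.tolist(), key=lambda a: fdi.ARCH_ORDER[jaw][a]
            )
        det_order = sorted(rows.tolist(), key=lambda r: (coms[r, 0], r))
        for r, a in zip(det_order, code_order):
            E2[r, fdi.JAW_COLUMNS[jaw][a]] = 1
    return E2


# --- stage 3: slot refinement ------------------------------------------------

def _placement_costs(
    dist: np.ndarray, djaw: np.ndarray, combos: np.ndarray, metric: str
) -> np.ndarray:
    """f3 cost (unordered pairs, x2) of each order-preserving placement.

    ``dist`` is the k x k COM distance matrix of the jaw's detections in x
    order, ``djaw`` the 16 x 16 prior in arch order, ``combos`` an (M, k)
    array of strictly increasing slot tuples.
    """
    k = dist.shape[0]
    costs = np.zeros(len(combos))
    for i, j in itertools.combinations(range(k), 2):
        dij = djaw[combos[:, i], combos[:, j]]
        term = _discrepancy(dist[i, j] - dij, metric)
        term = np.where(np.isnan(dij), 0.0, term)
        costs += 2.0 * term
    return costs


def stage3_slots(
    E2: np.ndarray,
    scene: ArchScene,
    prior: DistancePrior,
    config: LabelingConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Exhaustive order-preserving slot placement minimizing f3.

    For each jaw, the sorted detection sequence is injected into the 16 arch
    slots in every order-preserving way (C(16, k) placements, at most 12,870)
    and the placement with the lowest distance-prior discrepancy wins; ties
    go to the lexicographically smallest slot tuple.  Blank slots model
    missing teeth.
    """
    E2 = validate_assignment(E2)
    coms = scene.coms()
    E3 = empty_assignment(len(E2))
    for jaw in (fdi.UPPER, fdi.LOWER):
        rows, local = _jaw_assignments(E2, jaw)
        if len(rows) == 0:
            continue
        # detections in arch (== x) order as established by stage 2
        order = np.argsort(local, kind="stable")
        rows = rows[order]
        if len(rows) > 16:
            warnings.warn(
                f"{len(rows)} detections in the {jaw} jaw exceed the 16 arch "
                "slots; surplus detections left unassigned",
                stacklevel=2,
            )
            rows = rows[:16]
        k = len(rows)
        pts = coms[rows]
        dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        djaw = prior.jaw_submatrix(jaw)
        combos = np.array(list(itertools.combinations(range(16), k)))
        costs = _placement_costs(dist, djaw, combos, config.f3_metric)
        best = combos[int(np.argmin(costs))]
        for r, slot in zip(rows, best):
            E3[r, fdi.JAW_COLUMNS[jaw][slot]] = 1
    return E3


# --- full pipeline -----------------------------------------------------------

@dataclass
class LabelingResult:
    """Assignments and penalties of the three refinement stages."""

    E1: np.ndarray
    E2: np.ndarray
    E3: np.ndarray
    penalties: dict[str, float]
    labels: dict[int, int | None]   # detection_id -> FDI code or None

    def codes(self) -> list[int | None]:
        return assignment_codes(self.E3)


def label_teeth(
    scene: ArchScene,
    prior: DistancePrior,
    weights: PenaltyWeights = PenaltyWeights(),
    config: LabelingConfig = DEFAULT_CONFIG,
) -> LabelingResult:
    """Run the three refinement stages and collect per-stage penalties."""
    if len(scene) == 0:
        raise ValueError("cannot label an empty scene")
    jaws = _detection_jaws(scene, config)
    coms = scene.coms()
    E1 = stage1_greedy(scene, weights, config)
    E2 = stage2_sort(E1, scene, config)
    E3 = stage3_slots(E2, scene, prior, config)
    penalties = {
        "f1": penalty_f1(
            E1, coms, scene.watershed_z, weights, jaws, config.upper_above_watershed
        ),
        "f2": penalty_f2(E2, coms, config.order_by_arch_index),
        "f3": penalty_f3(E3, coms, prior, config.f3_metric),
    }
    labels = {
        d.detection_id: code
        for d, code in zip(scene.detections, assignment_codes(E3))
    }
    return LabelingResult(E1=E1, E2=E2, E3=E3, penalties=penalties, labels=labels)


# --- brute-force oracle ------------------------------------------------------

def brute_force_label(
    scene: ArchScene,
    prior: DistancePrior,
    weights: PenaltyWeights = PenaltyWeights(),
    max_n: int = 8,
    config: LabelingConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Exhaustive assignment search, for verifying the staged heuristic.

    Within the jaw indicated by each COM's watershed side (or the jaw hint),
    every injective partial assignment of detections to the jaw's 16 codes is
    enumerated and the one minimizing (f1, f2, f3) lexicographically is
    returned; ties break on the smallest per-detection arch-index vector
    (unassigned rows sort last).  Guarded by ``max_n`` per jaw — the space
    grows factorially.
    """
    jaws = _detection_jaws(scene, config)
    coms = scene.coms()
    E = empty_assignment(len(scene))
    for jaw in (fdi.UPPER, fdi.LOWER):
        dets = [i for i in range(len(scene)) if jaws[i] == jaw]
        n = len(dets)
        if n == 0:
            continue
        if n > max_n:
            raise ValueError(
                f"{n} detections in the {jaw} jaw exceed max_n={max_n}; "
                "exhaustive enumeration refused"
            )
        x = coms[dets, 0]
        pts = coms[dets]
        dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        djaw = prior.jaw_submatrix(jaw)
        best_key = None
        best_assign: dict[int, int] = {}
        for subset in itertools.chain.from_iterable(
            itertools.combinations(range(n), k) for k in range(n + 1)
        ):
            k = len(subset)
            for perm in itertools.permutations(range(16), k):
                # f1: injective & same-jaw, so only the unassigned term remains
                f1 = weights.lambda13 * (n - k)
                f2 = 0
                for (ia, sa), (ib, sb) in itertools.combinations(
                    zip(subset, perm), 2
                ):
                    if (x[ia] > x[ib]) != (sa > sb):
                        f2 += 2
                f3 = 0.0
                for (ia, sa), (ib, sb) in itertools.combinations(
                    zip(subset, perm), 2
                ):
                    dpair = djaw[sa, sb]
                    if not np.isnan(dpair):
                        f3 += 2.0 * float(
                            _discrepancy(
                                np.array(dist[ia, ib] - dpair), config.f3_metric
                            )
                        )
                vec = [16] * n
                for ia, sa in zip(subset, perm):
                    vec[ia] = sa
                key = (f1, f2, f3, tuple(vec))
                if best_key is None or key < best_key:
                    best_key = key
                    best_assign = dict(zip(subset, perm))
        for local_i, slot in best_assign.items():
            E[dets[local_i], fdi.JAW_COLUMNS[jaw][slot]] = 1
    return E


# --- prior estimation --------------------------------------------------------

def estimate_distance_prior(scenes: list[ArchScene]) -> DistancePrior:
    """Mean same-jaw inter-tooth COM distance over ground-truth-labeled scenes.

    Every scene must carry ``fdi_labels``.  Entries for code pairs never
    co-observed stay NaN with support 0; cross-jaw entries are never
    estimated; the diagonal is 0 by definition.
    """
    if not scenes:
        raise ValueError("at least one labeled scene is required")
    sums = np.zeros((C, C))
    counts = np.zeros((C, C), int)
    for scene in scenes:
        if scene.fdi_labels is None:
            raise ValueError("scene lacks ground-truth FDI labels")
        com_of = {d.detection_id: d.com for d in scene.detections}
        items = [
            (fdi.CODE_TO_COLUMN[code], com_of[det_id])
            for det_id, code in scene.fdi_labels.items()
        ]
        for (c1, p1), (c2, p2) in itertools.combinations(items, 2):
            if fdi.JAW_OF_COLUMN[c1] != fdi.JAW_OF_COLUMN[c2]:
                continue
            dist = float(np.linalg.norm(p1 - p2))
            sums[c1, c2] += dist
            sums[c2, c1] += dist
            counts[c1, c2] += 1
            counts[c2, c1] += 1
    with np.errstate(invalid="ignore"):
        d = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(counts, 0)
    return DistancePrior(d=d, support=counts)
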