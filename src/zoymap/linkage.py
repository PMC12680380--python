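"""Linkage-group assembly and marker ordering for an F2 intercross.

Two-point recombination fractions are estimated by maximum likelihood under
the F2 joint-genotype model (independent gametes: a parental gamete has
probability (1-r)/2 and a recombinant r/2, giving e.g.
P(AA,AA) = (1-r)^2/4 and P(AB,AB) = ((1-r)^2 + r^2)/2).  Partial codes
contribute the summed probability of their compatible genotypes; pairs with
a missing member are skipped.  The likelihood optionally mixes in a
genotyping-error rate (P(observed | true) confusion), the same device the
classical mappers use for error detection; the default is the error-free
model.

Groups are connected components of the LOD-thresholded linkage graph.
Orders come from seriation (first principal coordinate of the Kosambi
distance matrix) polished by 2-opt moves minimizing SARF, with exhaustive
search for small groups; markers not separated by recombination are ordered
by physical position.  Reported distances are Kosambi centimorgans.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genocode import CODES, CODE_INDEX, ScoreMatrix

_LN10 = math.log(10.0)
_U = CODE_INDEX["U"]


# ---------------------------------------------------------------------------
# Map functions
# ---------------------------------------------------------------------------

def kosambi_cm(r, max_cm: float = 50.0):
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)), capped near r = 0.5."""
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    out = np.empty_like(r)
    near_half = r >= 0.5 - 1e-12
    with np.errstate(divide="ignore"):
        out[~near_half] = 25.0 * np.log((1 + 2 * r[~near_half]) / (1 - 2 * r[~near_half]))
    if near_half.any():
        warnings.warn("recombination fraction at 0.5; distance capped", stacklevel=2)
        out[near_half] = max_cm
    out = np.minimum(out, max_cm) if max_cm is not None else out
    return float(out[0]) if scalar else out


def kosambi_r(d_cm):
    """Inverse Kosambi: r = tanh(2d/100)/2."""
    d = np.asarray(d_cm, dtype=float)
    out = np.tanh(2.0 * d / 100.0) / 2.0
    return float(out) if out.ndim == 0 else out


def haldane_r(d_cm):
    """Inverse Haldane: r = (1 - e^(-2d/100))/2 (no interference)."""
    d = np.asarray(d_cm, dtype=float)
    out = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# F2 joint-genotype likelihood
# ---------------------------------------------------------------------------

def f2_joint_probs(r: float) -> np.ndarray:
    """3x3 joint genotype probabilities of two linked markers in an F2.

    Genotypes indexed 0=AA, 1=AB, 2=BB.  Built from independent maternal and
    paternal gametes of the doubly heterozygous F1 in coupling phase.
    """
    # gamete haplotypes over (locus1, locus2): alleles 0/1
    haps = [(0, 0), (1, 1), (0, 1), (1, 0)]
    probs = [(1 - r) / 2, (1 - r) / 2, r / 2, r / 2]
    out = np.zeros((3, 3))
    for (a1, a2), p in zip(haps, probs):
        for (b1, b2), q in zip(haps, probs):
            out[a1 + b1, a2 + b2] += p * q
    return out


def observation_matrix(error_rate: float = 0.0) -> np.ndarray:
    """P(observed code | true genotype), shape (3 genotypes, 6 codes).

    Definite codes are right with probability 1-e, miscoded to either other
    definite code with e/2 each.  Partial codes inherit the mass of their
    compatible definite codes; U is uninformative (likelihood 1).
    """
    e = error_rate
    O = np.zeros((3, 6))
    definite = {"A": 0, "H": 1, "B": 2}  # genotype index of each definite code
    for code, g in definite.items():
        for true_g in range(3):
            O[true_g, CODE_INDEX[code]] = (1 - e) if true_g == g else e / 2
    O[:, CODE_INDEX["C"]] = O[:, CODE_INDEX["B"]] + O[:, CODE_INDEX["H"]]
    O[:, CODE_INDEX["D"]] = O[:, CODE_INDEX["A"]] + O[:, CODE_INDEX["H"]]
    O[:, CODE_INDEX["U"]] = 1.0
    return O


class F2PairModel:
    """Cached grid of log pair-probabilities for fast two-point estimation."""

    def __init__(self, error_rate: float = 0.0, grid_step: float = 0.001):
        self.error_rate = error_rate
        self.grid = np.arange(0.0, 0.5 + grid_step / 2, grid_step)
        self._O = observation_matrix(error_rate)
        logs = np.empty((len(self.grid), 36))
        for i, r in enumerate(self.grid):
            logs[i] = self._log_pair_probs(r)
        self._log_grid = logs

    def _log_pair_probs(self, r: float) -> np.ndarray:
        J = f2_joint_probs(r)
        P = self._O.T @ J @ self._O          # (6 codes, 6 codes)
        return np.log(np.maximum(P, 1e-300)).ravel()

    def loglik(self, counts36: np.ndarray, r: float) -> float:
        return float(self._log_pair_probs(r) @ counts36)

    def grid_logliks(self, counts36: np.ndarray) -> np.ndarray:
        return self._log_grid @ counts36


_MODELS: dict[tuple, F2PairModel] = {}


def _pair_model(error_rate: float) -> F2PairModel:
    key = (round(error_rate, 12),)
    if key not in _MODELS:
        _MODELS[key] = F2PairModel(error_rate)
    return _MODELS[key]


@dataclass(frozen=True)
class RFEstimate:
    r_hat: float
    lod: float
    n_informative: int
    valid: bool = True


def pair_counts(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """36-vector of joint code counts, skipping pairs with a U member."""
    mask = (v1 != _U) & (v2 != _U)
    return np.bincount(v1[mask] * 6 + v2[mask], minlength=36).astype(float)


def encode_scores(values) -> np.ndarray:
    """Map an iterable of score characters to integer codes."""
    return np.fromiter((CODE_INDEX[c] for c in values), dtype=np.int8,
                       count=len(values))


def estimate_rf(v1, v2, error_rate: float = 0.0) -> RFEstimate:
    """Maximum-likelihood recombination fraction and linkage LOD.

    Accepts score vectors as characters or pre-encoded integers.  The MLE is
    located on a 0.001 grid and refined by bounded 1-D search; the LOD is
    log10 L(r_hat) / L(0.5).  Fewer than two jointly informative
    individuals yields a flagged, undefined estimate.
    """
    a = encode_scores(v1) if not isinstance(v1, np.ndarray) or v1.dtype.kind != "i" else v1
    b = encode_scores(v2) if not isinstance(v2, np.ndarray) or v2.dtype.kind != "i" else v2
    if len(a) != len(b):
        raise ValueError("score vectors must have the same length")
    counts = pair_counts(a, b)
    return estimate_rf_from_counts(counts, error_rate)


def estimate_rf_from_counts(counts36: np.ndarray, error_rate: float = 0.0) -> RFEstimate:
    n_inf = int(counts36.sum())
    if n_inf < 2:
        return RFEstimate(float("nan"), 0.0, n_inf, valid=False)
    model = _pair_model(error_rate)
    lls = model.grid_logliks(counts36)
    i = int(np.argmax(lls))
    lo = model.grid[max(i - 1, 0)]
    hi = model.grid[min(i + 1, len(model.grid) - 1)]
    candidates = [(model.grid[i], lls[i])]
    if hi > lo:
        res = minimize_scalar(
            lambda r: -model.loglik(counts36, r), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        candidates.append((float(res.x), -float(res.fun)))
    for r_edge in (lo, hi):
        candidates.append((float(r_edge), model.loglik(counts36, r_edge)))
    r_hat, ll_hat = max(candidates, key=lambda t: t[1])
    ll_null = model.loglik(counts36, 0.5)
    lod = max((ll_hat - ll_null) / _LN10, 0.0)
    return RFEstimate(min(max(r_hat, 0.0), 0.5), lod, n_inf)


class PairwiseRF:
    """Caching provider of pairwise RF estimates over a ScoreMatrix."""

    def __init__(self, scores: ScoreMatrix, error_rate: float = 0.0):
        self.marker_ids = list(scores.marker_ids)
        self._index = {m: i for i, m in enumerate(self.marker_ids)}
        prog = scores.progeny.to_numpy()
        self._enc = np.empty(prog.shape, dtype=np.int8)
        for code, idx in CODE_INDEX.items():
            self._enc[prog == code] = idx
        self.error_rate = error_rate
        self._cache: dict[tuple[int, int], RFEstimate] = {}

    def estimate(self, m1: str, m2: str) -> RFEstimate:
        i, j = self._index[m1], self._index[m2]
        key = (i, j) if i < j else (j, i)
        if key not in self._cache:
            counts = pair_counts(self._enc[key[0]], self._enc[key[1]])
            self._cache[key] = estimate_rf_from_counts(counts, self.error_rate)
        return self._cache[key]

    def r(self, m1: str, m2: str) -> float:
        est = self.estimate(m1, m2)
        return est.r_hat if est.valid else 0.5

    def lod(self, m1: str, m2: str) -> float:
        return self.estimate(m1, m2).lod

    def distance_matrix(self, markers: list[str], max_cm: float = 50.0) -> np.ndarray:
        m = len(markers)
        D = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                D[i, j] = D[j, i] = kosambi_cm(
                    min(self.r(markers[i], markers[j]), 0.5 - 1e-9), max_cm
                )
        return D


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def group_markers(
    rf: PairwiseRF, min_lod: float = 12.0, no_map_cm: float = 15.0
) -> tuple[list[list[str]], list[str]]:
    """Linkage groups as connected components of the LOD-thresholded graph.

    An edge joins two markers when their linkage LOD is at least ``min_lod``.
    Within each component, a marker whose nearest linked neighbour lies
    beyond ``no_map_cm`` (Kosambi-transformed r-hat) is set aside as
    unplaceable, as are singletons and markers with no valid estimates.
    """
    markers = rf.marker_ids
    G = nx.Graph()
    G.add_nodes_from(markers)
    for i, m1 in enumerate(markers):
        for m2 in markers[i + 1:]:
            est = rf.estimate(m1, m2)
            if est.valid and est.lod >= min_lod:
                G.add_edge(m1, m2)
    groups, ungrouped = [], []
    for comp in nx.connected_components(G):
        comp = [m for m in markers if m in comp]  # stable order
        if len(comp) == 1:
            ungrouped.extend(comp)
            continue
        placed = []
        for m in comp:
            nearest = min(
                kosambi_cm(min(rf.r(m, other), 0.5 - 1e-9), max_cm=1e9)
                for other in comp if other != m
            )
            (placed if nearest <= no_map_cm else ungrouped).append(m)
        if len(placed) >= 2:
            groups.append(placed)
        else:
            ungrouped.extend(placed)
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups, ungrouped


def _twin(marker_id: str) -> str:
    return marker_id[:-1] if marker_id.endswith("r") else marker_id + "r"


def dedupe_mirror_groups(
    groups: list[list[str]],
) -> tuple[list[list[str]], pd.DataFrame]:
    """Collapse mirror-image groups created by phase-unknown duplication.

    Two groups whose marker sets correspond 1:1 under the "r" pairing are
    the two phase readings of one chromosome; the copy with more
    non-reversed markers is retained (ties broken lexicographically).  A
    marker co-occurring with its own twin inside one group is reported as a
    conflict but both copies are kept for the ordering stage.
    """
    sets = [frozenset(g) for g in groups]
    set_index = {s: i for i, s in enumerate(sets)}
    dropped: set[int] = set()
    report_rows = []
    for i, s in enumerate(sets):
        if i in dropped:
            continue
        for m in s:
            if _twin(m) in s:
                report_rows.append(
                    {"group": i, "marker": m, "event": "twin-in-same-group"}
                )
        mirror = frozenset(_twin(m) for m in s)
        j = set_index.get(mirror)
        if j is not None and j != i and j not in dropped and i not in dropped:
            def n_plain(idx):
                return sum(not m.endswith("r") for m in sets[idx])
            a, b = sorted([i, j])
            if n_plain(a) > n_plain(b):
                keep, drop = a, b
            elif n_plain(a) < n_plain(b):
                keep, drop = b, a
            else:
                keep, drop = (a, b) if sorted(sets[a]) <= sorted(sets[b]) else (b, a)
            dropped.add(drop)
            for m in sets[drop]:
                report_rows.append(
                    {"group": drop, "marker": m, "event": "mirror-dropped",
                     "retained_group": keep}
                )
    kept = [g for i, g in enumerate(groups) if i not in dropped]
    return kept, pd.DataFrame(report_rows)


# ---------------------------------------------------------------------------
# Ordering
# ---------------------------------------------------------------------------

def sarf(order: list[str], rf: PairwiseRF) -> float:
    """Sum of adjacent recombination fractions — the ordering objective."""
    return float(sum(rf.r(a, b) for a, b in zip(order[:-1], order[1:])))


def _seriation_order(markers: list[str], rf) -> list[str]:
    """Framework order from the first principal coordinate of the distance
    matrix (classical MDS)."""
    m = len(markers)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = kosambi_cm(
                min(rf.r(markers[i], markers[j]), 0.5 - 1e-9), max_cm=80.0
            )
    n = len(markers)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    coord = v[:, -1] * math.sqrt(max(w[-1], 0.0))
    return [markers[i] for i in np.argsort(coord, kind="stable")]


def _two_opt(order: list[str], rf: PairwiseRF) -> list[str]:
    order = list(order)
    n = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(1, n - 1):
            for j in range(i + 1, n):
                before = 0.0
                after = 0.0
                before += rf.r(order[i - 1], order[i])
                after += rf.r(order[i - 1], order[j])
                if j + 1 < n:
                    before += rf.r(order[j], order[j + 1])
                    after += rf.r(order[i], order[j + 1])
                if after < before - 1e-12:
                    order[i:j + 1] = reversed(order[i:j + 1])
                    improved = True
    return order


def _physical_tiebreak(order: list[str], rf: PairwiseRF,
                       meta: pd.DataFrame) -> list[str]:
    """Reorder zero-recombination windows by (scaffold, bp) when that does
    not increase SARF."""
    order = list(order)
    i = 0
    while i < len(order) - 1:
        j = i
        while j < len(order) - 1 and rf.r(order[j], order[j + 1]) < 1e-9:
            j += 1
        if j > i:
            window = order[i:j + 1]
            resorted = sorted(
                window, key=lambda m: (str(meta.at[m, "scaffold"]), int(meta.at[m, "bp"]))
            )
            trial = order[:i] + resorted + order[j + 1:]
            if sarf(trial, rf) <= sarf(order, rf) + 1e-12:
                order = trial
        i = j + 1
    return order


def _orient(order: list[str], meta: pd.DataFrame) -> list[str]:
    scaffolds = [str(meta.at[m, "scaffold"]) for m in order]
    majority = pd.Series(scaffolds).mode().iloc[0]
    on_major = [m for m in order if str(meta.at[m, "scaffold"]) == majority]
    if len(on_major) >= 2:
        if int(meta.at[on_major[0], "bp"]) > int(meta.at[on_major[-1], "bp"]):
            return order[::-1]
    return order


def order_markers(
    markers: list[str],
    rf: PairwiseRF,
    meta: pd.DataFrame | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    exhaustive_limit: int = 8,
) -> list[str]:
    """Order one linkage group's markers by SARF minimization.

    Groups up to ``exhaustive_limit`` markers are solved exactly by
    enumeration; larger groups start from a seriation framework (first
    principal coordinate of the Kosambi distance matrix) and are polished by
    2-opt with seeded random restarts.  Markers not separated by any
    recombination event are then ordered by physical (scaffold, bp)
    position, and the group is oriented so the first marker has the smaller
    physical position on the majority scaffold.
    """
    if len(markers) < 2:
        return list(markers)
    if len(markers) == 2:
        order = list(markers)
    elif len(markers) <= exhaustive_limit:
        best, best_s = None, math.inf
        for perm in itertools.permutations(markers):
            if perm[0] > perm[-1]:
                continue  # skip reversals
            s = sarf(list(perm), rf)
            if s < best_s - 1e-15:
                best, best_s = list(perm), s
        order = best
    else:
        rng = np.random.default_rng(seed)
        base = _seriation_order(markers, rf)
        best = _two_opt(base, rf)
        best_s = sarf(best, rf)
        for _ in range(n_restarts):
            cand = list(base)
            rng.shuffle(cand)
            cand = _two_opt(cand, rf)
            s = sarf(cand, rf)
            if s < best_s - 1e-12:
                best, best_s = cand, s
        order = best
    if meta is not None:
        order = _physical_tiebreak(order, rf, meta)
        order = _orient(order, meta)
    return order


# ---------------------------------------------------------------------------
# Double recombinants and map distances
# ---------------------------------------------------------------------------

_DEFINITE_CODES = {"A", "H", "B"}


def count_double_recombinants(order: list[str], scores: ScoreMatrix) -> np.ndarray:
    """Per-marker count of X-Y-X patterns across adjacent marker triples.

    For each internal marker, counts progeny whose flanking codes are equal,
    definite, and definitely different from the middle code — the signature
    of two crossovers in a short interval, usually a genotyping error.
    """
    grid = scores.progeny.loc[order].to_numpy()
    m = len(order)
    counts = np.zeros(m, dtype=int)
    for k in range(1, m - 1):
        left, mid, right = grid[k - 1], grid[k], grid[k + 1]
        definite = (
            np.isin(left, list(_DEFINITE_CODES))
            & np.isin(mid, list(_DEFINITE_CODES))
            & np.isin(right, list(_DEFINITE_CODES))
        )
        counts[k] = int(np.sum(definite & (left == right) & (left != mid)))
    return counts


def filter_double_recombinants(
    order: list[str], scores: ScoreMatrix, max_events: int = 10
) -> tuple[list[str], list[str]]:
    """Drop markers with more than ``max_events`` double recombinations."""
    counts = count_double_recombinants(order, scores)
    removed = [m for m, c in zip(order, counts) if c > max_events]
    kept = [m for m in order if m not in set(removed)]
    return kept, removed


def physical_polish(order: list[str], scores: ScoreMatrix,
                    meta: pd.DataFrame) -> list[str]:
    """Swap adjacent markers toward assembly order when this does not
    increase the implied recombination events.

    Statistical ordering can transpose tightly linked neighbours whose
    estimated r-hats are inverted by sampling noise; such transpositions
    show up as spurious double recombinations.  Adjacent same-scaffold pairs
    out of physical order are swapped whenever the total double-recombination
    count does not grow — the automated analogue of verifying marker order
    against the genome assembly.
    """
    order = list(order)
    total = int(count_double_recombinants(order, scores).sum())
    improved = True
    while improved:
        improved = False
        for k in range(len(order) - 1):
            a, b = order[k], order[k + 1]
            if str(meta.at[a, "scaffold"]) != str(meta.at[b, "scaffold"]):
                continue
            if int(meta.at[a, "bp"]) <= int(meta.at[b, "bp"]):
                continue
            trial = order[:k] + [b, a] + order[k + 2:]
            trial_total = int(count_double_recombinants(trial, scores).sum())
            if trial_total <= total:
                order, total = trial, trial_total
                improved = True
    return order


@dataclass
class LinkageGroup:
    """An ordered linkage group with adjacent r-hats and Kosambi positions."""

    name: str
    markers: list[str]
    adj_r: np.ndarray
    cm: np.ndarray
    double_recomb: np.ndarray | None = None

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1]) if len(self.cm) else 0.0

    def reversed_copy(self) -> "LinkageGroup":
        cm = self.cm[-1] - self.cm[::-1]
        return LinkageGroup(self.name, self.markers[::-1], self.adj_r[::-1], cm,
                            None if self.double_recomb is None
                            else self.double_recomb[::-1])


def map_distances(order: list[str], rf: PairwiseRF,
                  max_cm: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """Adjacent r-hats and cumulative Kosambi cM positions (first marker 0)."""
    adj = np.array([rf.r(a, b) for a, b in zip(order[:-1], order[1:])])
    d = np.array([kosambi_cm(min(r, 0.5), max_cm) for r in adj])
    return adj, np.concatenate([[0.0], np.cumsum(d)])


@dataclass
class LinkageMap:
    groups: list[LinkageGroup]
    ungrouped: list[str]
    meta: pd.DataFrame
    phase_report: pd.DataFrame | None = None
    bin_map: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            overlap = seen & set(g.markers)
            if overlap:
                raise ValueError(f"marker(s) in two groups: {sorted(overlap)[:3]}")
            seen |= set(g.markers)

    @property
    def n_markers(self) -> int:
        return sum(len(g.markers) for g in self.groups)

    @property
    def total_cm(self) -> float:
        return sum(g.length_cm for g in self.groups)

    def marker_table(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for m, pos in zip(g.markers, g.cm):
                rec = {"lg": g.name, "marker_id": m, "cm": float(pos)}
                if m in self.meta.index:
                    rec["scaffold"] = self.meta.at[m, "scaffold"]
                    rec["bp"] = int(self.meta.at[m, "bp"])
                    rec["phase_flag"] = bool(self.meta.at[m, "reversed"])
                rows.append(rec)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        df = self.marker_table()
        if self.bin_map:
            df["bin_members"] = [
                ",".join(self.bin_map.get(m, [m])) for m in df["marker_id"]
            ]
        df.to_csv(path, sep="\t", index=False)


def build_linkage_map(
    scores: ScoreMatrix,
    min_lod: float = 12.0,
    no_map_cm: float = 15.0,
    max_double_recomb: int = 10,
    error_rate: float = 0.0,
    n_restarts: int = 5,
    seed: int = 0,
    bin_map: dict[str, list[str]] | None = None,
) -> LinkageMap:
    """Full chain: group, dedupe mirrors, order, filter, Kosambi distances."""
    rf = PairwiseRF(scores, error_rate)
    raw_groups, ungrouped = group_markers(rf, min_lod, no_map_cm)
    groups, phase_report = dedupe_mirror_groups(raw_groups)
    out = []
    for gi, members in enumerate(groups):
        order = order_markers(members, rf, scores.meta, n_restarts, seed + gi)
        order = physical_polish(order, scores, scores.meta)
        order, removed = filter_double_recombinants(order, scores, max_double_recomb)
        ungrouped.extend(removed)
        if len(order) < 2:
            ungrouped.extend(order)
            continue
        adj, cm = map_distances(order, rf)
        dr = count_double_recombinants(order, scores)
        out.append(LinkageGroup(f"LG{gi + 1:02d}", order, adj, cm, dr))
    return LinkageMap(out, ungrouped, scores.meta, phase_report, bin_map)


def rescue_distorted_regions(
    lmap: LinkageMap,
    scores_with_removed: ScoreMatrix,
    removed_markers: list[str],
    scaffold_to_lg: dict[str, str],
    error_rate: float = 0.0,
    seed: int = 0,
) -> LinkageMap:
    """Re-admit distortion-filtered markers into their physical linkage groups.

    Markers from the removal list whose scaffold physically belongs to a
    target LG are added back and that LG is re-ordered without the
    chi-squared filter.  Markers without a physical assignment are skipped
    with a warning.
    """
    rf = PairwiseRF(scores_with_removed, error_rate)
    by_lg: dict[str, list[str]] = {}
    for m in removed_markers:
        if m not in scores_with_removed.meta.index:
            warnings.warn(f"marker {m} has no physical assignment; skipped")
            continue
        scaffold = str(scores_with_removed.meta.at[m, "scaffold"])
        lg = scaffold_to_lg.get(scaffold)
        if lg is None:
            warnings.warn(f"marker {m}: scaffold {scaffold} not assigned to an LG; skipped")
            continue
        by_lg.setdefault(lg, []).append(m)
    new_groups = []
    for gi, g in enumerate(lmap.groups):
        extra = by_lg.get(g.name, [])
        if not extra:
            new_groups.append(g)
            continue
        members = g.markers + extra
        order = order_markers(members, rf, scores_with_removed.meta, seed=seed + gi)
        order = physical_polish(order, scores_with_removed, scores_with_removed.meta)
        adj, cm = map_distances(order, rf)
        dr = count_double_recombinants(order, scores_with_removed)
        new_groups.append(LinkageGroup(g.name, order, adj, cm, dr))
    return LinkageMap(new_groups, lmap.ungrouped, scores_with_removed.meta,
                      lmap.phase_report, lmap.bin_map)
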