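"""Binary-trait QTL interval mapping by Haley-Knott regression.

Conditional QTL genotype probabilities on a grid (default every 2.5 cM plus
the marker positions) are computed per chromosome by a three-state
({AA, AB, BB}) hidden-Markov forward-backward pass with the F2 stationary
distribution (1/4, 1/2, 1/4).  Transition probabilities come from
Haldane-inverted inter-position distances with independent gametes (the
no-interference convention interval mappers use, even though reported map
distances are Kosambi).  At each position the phenotype is regressed by
least squares on the additive (P(BB) - P(AA)) and dominance (P(AB))
regressors plus optional marker covariates;
LOD = (n/2) log10(RSS0 / RSS1) against the covariate-only null.  Genome-wide
significance comes from permuting phenotype labels jointly across all
chromosomes.  Binary phenotypes (green = 1 / purple = 2) are analysed by
least squares, which is what Haley-Knott regression does; any affine
recoding of the phenotype leaves the LOD curve unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genocode import ConfigError, ScoreMatrix
from .linkage import haldane_r

_LN10 = math.log(10.0)

STATES = ("AA", "AB", "BB")
_PI = np.array([0.25, 0.5, 0.25])


def transition_matrix(r: float) -> np.ndarray:
    """F2 genotype transition matrix for recombination fraction r.

    Each of the two gametes independently switches parental origin with
    probability r between positions.
    """
    s = 1.0 - r
    return np.array([
        [s * s, 2 * r * s, r * r],
        [r * s, s * s + r * r, r * s],
        [r * r, 2 * r * s, s * s],
    ])


def _emission_table(eps: float) -> dict[str, np.ndarray]:
    return {
        "A": np.array([1 - eps, eps / 2, eps / 2]),
        "H": np.array([eps / 2, 1 - eps, eps / 2]),
        "B": np.array([eps / 2, eps / 2, 1 - eps]),
        "C": np.array([eps, 1 - eps, 1 - eps]),      # "B or H"
        "D": np.array([1 - eps, 1 - eps, eps]),      # "A or H"
        "U": np.array([1.0, 1.0, 1.0]),
    }


@dataclass
class GenoProbGrid:
    """Per-position, per-individual QTL genotype probabilities.

    ``positions`` has columns lg, cm, marker_id ("" for pure grid points);
    ``probs`` has shape (n_positions, n_individuals, 3) and rows summing
    to 1.
    """

    positions: pd.DataFrame
    probs: np.ndarray
    individuals: list[str]
    step_cm: float
    eps: float

    def chrom_slice(self, lg: str) -> np.ndarray:
        return np.flatnonzero((self.positions["lg"] == lg).to_numpy())


def genotype_probs(
    markers: pd.DataFrame,
    scores: ScoreMatrix,
    step_cm: float = 2.5,
    eps: float = 1e-4,
) -> GenoProbGrid:
    """Forward-backward conditional genotype probabilities on the scan grid.

    ``markers`` is a long-format map table with columns ``lg``,
    ``marker_id`` and ``cm`` (e.g. ``LinkageMap.marker_table()`` or
    ``GenomeSpec.marker_table()``).  Scores for markers absent from the
    matrix are ignored; grid points fall every ``step_cm`` from 0 to the
    last marker, merged with the marker positions themselves.
    """
    if step_cm <= 0:
        raise ConfigError("step_cm must be positive")
    if not 0 <= eps < 0.5:
        raise ConfigError("eps must lie in [0, 0.5)")
    individuals = scores.progeny_columns
    n = len(individuals)
    emit = _emission_table(eps)
    grid_emissions = []
    pos_rows = []

    for lg, sub in markers.groupby("lg", sort=False):
        sub = sub.sort_values("cm")
        sub = sub[sub["marker_id"].isin(scores.marker_ids)]
        if sub.empty:
            continue
        last = float(sub["cm"].max())
        grid = np.arange(0.0, last + 1e-9, step_cm)
        pos = np.unique(np.round(np.concatenate([grid, sub["cm"].to_numpy(float)]), 6))
        E = np.ones((len(pos), n, 3))
        marker_at = [""] * len(pos)
        for _, row in sub.iterrows():
            idx = int(np.searchsorted(pos, round(float(row["cm"]), 6)))
            codes = scores.scores.loc[row["marker_id"], individuals]
            E[idx] *= np.stack([emit[c] for c in codes])
            marker_at[idx] = row["marker_id"] if not marker_at[idx] else marker_at[idx]
        # forward-backward with per-step scaling
        P = len(pos)
        alpha = np.empty((P, n, 3))
        a = _PI * E[0]
        alpha[0] = a / a.sum(axis=1, keepdims=True)
        trans = [transition_matrix(haldane_r(pos[t + 1] - pos[t])) for t in range(P - 1)]
        for t in range(1, P):
            a = (alpha[t - 1] @ trans[t - 1]) * E[t]
            alpha[t] = a / a.sum(axis=1, keepdims=True)
        beta = np.ones((P, n, 3))
        for t in range(P - 2, -1, -1):
            b = (beta[t + 1] * E[t + 1]) @ trans[t].T
            beta[t] = b / b.sum(axis=1, keepdims=True)
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        grid_emissions.append(post)
        for p, m in zip(pos, marker_at):
            pos_rows.append({"lg": lg, "cm": float(p), "marker_id": m})

    if not pos_rows:
        raise ConfigError("no mapped markers with scores")
    return GenoProbGrid(
        pd.DataFrame(pos_rows), np.concatenate(grid_emissions, axis=0),
        individuals, step_cm, eps,
    )


# ---------------------------------------------------------------------------
# Haley-Knott regression
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    table: pd.DataFrame            # lg, cm, marker_id, lod
    n: int
    peak_lg: str
    peak_cm: float
    peak_marker: str
    peak_lod: float
    threshold: float | None = None
    interval: tuple[float, float] | None = None
    pve: float | None = None
    covariate_names: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "chromosome": self.peak_lg,
            "peak_marker": self.peak_marker,
            "peak_cm": self.peak_cm,
            "peak_lod": self.peak_lod,
            "lod_threshold": self.threshold,
            "interval_left_cm": None if self.interval is None else self.interval[0],
            "interval_right_cm": None if self.interval is None else self.interval[1],
            "pve_percent": None if self.pve is None else 100 * self.pve,
            "n": self.n,
        }])


def _prepare(grid: GenoProbGrid, phenotype, covariates):
    y = phenotype
    if isinstance(y, pd.Series):
        y = y.reindex(grid.individuals).to_numpy(float)
    else:
        y = np.asarray(y, dtype=float)
        if len(y) != len(grid.individuals):
            raise ConfigError("phenotype length must match individuals")
    keep = ~np.isnan(y)
    y = y[keep]
    covs = []
    names = []
    if covariates is not None:
        for i, c in enumerate(covariates):
            name = getattr(c, "name", None) or f"cov{i + 1}"
            arr = (c.reindex(grid.individuals).to_numpy(float)
                   if isinstance(c, pd.Series) else np.asarray(c, dtype=float))
            covs.append(arr[keep])
            names.append(str(name))
    X0 = np.column_stack([np.ones(keep.sum())] + covs)
    rank = np.linalg.matrix_rank(X0)
    if rank < X0.shape[1]:
        warnings.warn("collinear covariates dropped from the null model")
        q, r, piv = _qr_pivot(X0)
        keep_cols = piv[:rank]
        X0 = X0[:, sorted(keep_cols)]
    return y, X0, keep, names


def _qr_pivot(X):
    from scipy.linalg import qr
    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(resid @ resid)


def haley_knott_scan(
    grid: GenoProbGrid, phenotype, covariates=None
) -> ScanResult:
    """LOD curve of phenotype on conditional genotype probabilities.

    At every grid position the phenotype is regressed on the additive
    dosage contrast P(BB) - P(AA) and the dominance regressor P(AB), plus
    any covariates (which also form the null model), and
    LOD = (n/2) log10(RSS0/RSS1).
    """
    y, X0, keep, names = _prepare(grid, phenotype, covariates)
    n = len(y)
    rss0 = _rss(y, X0)
    probs = grid.probs[:, keep, :]
    lods = np.empty(len(grid.positions))
    for t in range(len(lods)):
        a = probs[t, :, 2] - probs[t, :, 0]
        d = probs[t, :, 1]
        X1 = np.column_stack([X0, a, d])
        rss1 = max(_rss(y, X1), 1e-300)
        lods[t] = (n / 2.0) * math.log10(max(rss0, 1e-300) / rss1)
    table = grid.positions.copy()
    table["lod"] = lods
    ipk = int(np.argmax(lods))
    peak = table.iloc[ipk]
    peak_marker = peak["marker_id"]
    if not peak_marker:
        sub = table[(table["lg"] == peak["lg"]) & (table["marker_id"] != "")]
        if not sub.empty:
            peak_marker = sub.iloc[(sub["cm"] - peak["cm"]).abs().argmin()]["marker_id"]
    return ScanResult(table, n, str(peak["lg"]), float(peak["cm"]),
                      str(peak_marker), float(lods[ipk]), covariate_names=names)


def permutation_threshold(
    grid: GenoProbGrid,
    phenotype,
    covariates=None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Genome-wide LOD significance threshold from phenotype permutations.

    Phenotype labels are permuted jointly across all chromosomes; the
    genome-wide maximum LOD is recorded per permutation and the empirical
    (1 - alpha) quantile (type-7 interpolation) is returned.
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    maxima = permutation_max_lods(grid, phenotype, covariates, n_perm, seed)
    return float(np.quantile(maxima, 1.0 - alpha))


def permutation_max_lods(
    grid: GenoProbGrid, phenotype, covariates=None, n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Per-permutation genome-wide maximum LODs (vectorized over perms)."""
    y, X0, keep, _ = _prepare(grid, phenotype, covariates)
    n = len(y)
    rng = np.random.default_rng(seed)
    Y = np.empty((n, n_perm))
    for j in range(n_perm):
        Y[:, j] = y[rng.permutation(n)]
    Q0, _ = np.linalg.qr(X0)
    yy = (Y * Y).sum(axis=0)
    q0y = Q0.T @ Y
    rss0 = np.maximum(yy - (q0y * q0y).sum(axis=0), 1e-300)
    max_lod = np.zeros(n_perm)
    probs = grid.probs[:, keep, :]
    for t in range(len(grid.positions)):
        a = probs[t, :, 2] - probs[t, :, 0]
        d = probs[t, :, 1]
        X1 = np.column_stack([X0, a, d])
        Q, _ = np.linalg.qr(X1)
        qy = Q.T @ Y
        rss1 = np.maximum(yy - (qy * qy).sum(axis=0), 1e-300)
        lod = (n / 2.0) * np.log10(rss0 / rss1)
        np.maximum(max_lod, lod, out=max_lod)
    return max_lod


@dataclass
class QtlFit:
    lod: float
    pve: float
    additive: float
    dominance: float
    rss0: float
    rss1: float


def fit_qtl(grid: GenoProbGrid, phenotype, peak, covariates=None) -> QtlFit:
    """Effect estimates and variance explained at a scan peak.

    ``peak`` is (lg, cm) or a :class:`ScanResult`.
    PVE = 1 - 10^(-2 LOD / n), which is algebraically identical to
    1 - RSS1/RSS0 of the peak regression.
    """
    if isinstance(peak, ScanResult):
        lg, cm = peak.peak_lg, peak.peak_cm
    else:
        lg, cm = peak
    y, X0, keep, _ = _prepare(grid, phenotype, covariates)
    n = len(y)
    if n == 0:
        raise ConfigError("no phenotyped individuals")
    pos = grid.positions
    idx_candidates = np.flatnonzero((pos["lg"] == lg).to_numpy())
    if len(idx_candidates) == 0:
        raise ConfigError(f"no scan positions on {lg}")
    local = idx_candidates[
        int(np.argmin(np.abs(pos.iloc[idx_candidates]["cm"].to_numpy() - cm)))
    ]
    a = grid.probs[local, keep, 2] - grid.probs[local, keep, 0]
    d = grid.probs[local, keep, 1]
    X1 = np.column_stack([X0, a, d])
    beta = np.linalg.lstsq(X1, y, rcond=None)[0]
    rss1 = max(_rss(y, X1), 1e-300)
    rss0 = max(_rss(y, X0), 1e-300)
    lod = (n / 2.0) * math.log10(rss0 / rss1)
    pve = 1.0 - 10.0 ** (-2.0 * lod / n)
    return QtlFit(lod, pve, float(beta[-2]), float(beta[-1]), rss0, rss1)


def support_interval(scan: ScanResult, drop: float = 1.5) -> tuple[float, float]:
    """LOD-drop support interval, expanded to the nearest flanking markers.

    The widest contiguous run of positions around the peak with
    LOD >= peak - drop is found on the peak chromosome, then each end is
    pushed outward to the nearest marker position.  A flat curve returns
    the whole chromosome with a warning.
    """
    tab = scan.table[scan.table["lg"] == scan.peak_lg].reset_index(drop=True)
    lod = tab["lod"].to_numpy()
    ipk = int(np.argmin(np.abs(tab["cm"].to_numpy() - scan.peak_cm)))
    thr = scan.peak_lod - drop
    left = ipk
    while left > 0 and lod[left - 1] >= thr:
        left -= 1
    right = ipk
    while right < len(tab) - 1 and lod[right + 1] >= thr:
        right += 1
    if left == 0 and right == len(tab) - 1 and lod.max() - lod.min() < drop:
        warnings.warn("flat LOD curve: support interval spans the whole chromosome")
    lcm, rcm = float(tab["cm"][left]), float(tab["cm"][right])
    markers = tab[tab["marker_id"] != ""]
    if not markers.empty:
        below = markers[markers["cm"] < lcm - 1e-9]
        above = markers[markers["cm"] > rcm + 1e-9]
        if not below.empty:
            lcm = float(below["cm"].iloc[-1])
        if not above.empty:
            rcm = float(above["cm"].iloc[0])
    return (lcm, rcm)
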