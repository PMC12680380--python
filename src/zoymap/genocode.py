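"""Variant calls to mapping scores, and every pre-mapping filter.

An F2 intercross between two (partially heterozygous) parents is genotyped
relative to the parent-1 reference genome.  Per-sample calls are converted to
single-letter mapping scores:

======  =============================================
code    meaning
======  =============================================
A       homozygous for the reference (parent 1) allele
B       homozygous for the alternate (parent 2) allele
H       heterozygous
C       "B or H" (partial call)
D       "A or H" (partial call)
U       unknown / missing
======  =============================================

The functions in this module take a :class:`VariantCallSet` (or a ready
:class:`ScoreMatrix`) through caller merging, GBS-tag consolidation,
reorientation to the cross, phase-unknown marker duplication, cosegregation
collapse and the missing-data / segregation-distortion filters, producing the
matrix the linkage module maps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

CODES = ("A", "B", "H", "C", "D", "U")
CODE_INDEX = {c: i for i, c in enumerate(CODES)}

#: genotype sets compatible with each score (genotypes 0=AA, 1=AB, 2=BB)
COMPATIBLE = {
    "A": frozenset({0}),
    "B": frozenset({2}),
    "H": frozenset({1}),
    "C": frozenset({1, 2}),
    "D": frozenset({0, 1}),
    "U": frozenset({0, 1, 2}),
}

_SET_TO_CODE = {
    frozenset({0}): "A",
    frozenset({2}): "B",
    frozenset({1}): "H",
    frozenset({1, 2}): "C",
    frozenset({0, 1}): "D",
    frozenset({0, 1, 2}): "U",
}

#: score substitution applied when flipping linkage phase (A<->B, C<->D)
PHASE_SWAP = {"A": "B", "B": "A", "C": "D", "D": "C", "H": "H", "U": "U"}

DEFINITE = ("A", "H", "B")


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration or unusable input."""


# ---------------------------------------------------------------------------
# ScoreMatrix container
# ---------------------------------------------------------------------------

META_COLUMNS = ["scaffold", "bp", "tag_id", "reversed"]


@dataclass
class ScoreMatrix:
    """Markers x individuals grid of mapping scores plus marker metadata.

    Parameters
    ----------
    scores
        DataFrame of single-character codes, index = marker ids, columns =
        individual ids (parents, F1 and progeny).
    meta
        DataFrame indexed like ``scores`` with columns ``scaffold``,
        ``bp`` (1-based physical position), ``tag_id`` and ``reversed``
        (True for the phase-flipped "r" copy of a marker).
    parents
        Column names of the two parents, in (P1, P2) role order, if present.
    f1
        Column name of the F1 individual, if present.
    """

    scores: pd.DataFrame
    meta: pd.DataFrame
    parents: tuple[str, str] | None = None
    f1: str | None = None

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.meta.index):
            raise ConfigError("scores and meta must share the same marker index")
        bad = set(np.unique(self.scores.to_numpy())) - set(CODES)
        if bad:
            raise ConfigError(f"invalid score codes: {sorted(bad)}")

    # -- basic views ------------------------------------------------------
    @property
    def marker_ids(self) -> pd.Index:
        return self.scores.index

    @property
    def progeny_columns(self) -> list[str]:
        drop = set(self.parents or ()) | ({self.f1} if self.f1 else set())
        return [c for c in self.scores.columns if c not in drop]

    @property
    def progeny(self) -> pd.DataFrame:
        return self.scores[self.progeny_columns]

    def copy(self) -> "ScoreMatrix":
        return ScoreMatrix(self.scores.copy(), self.meta.copy(), self.parents, self.f1)

    def subset(self, marker_ids) -> "ScoreMatrix":
        return ScoreMatrix(
            self.scores.loc[marker_ids], self.meta.loc[marker_ids], self.parents, self.f1
        )

    def code_counts(self, marker_id: str) -> dict[str, int]:
        row = self.scores.loc[marker_id, self.progeny_columns]
        vc = row.value_counts()
        return {c: int(vc.get(c, 0)) for c in CODES}

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write the matrix as tab-separated text.

        Layout: marker_id, scaffold, bp_position, tag_id, reversed, then one
        column per individual (parents and F1 first if known).
        """
        cols = list(self.scores.columns)
        out = self.meta.copy()
        out.insert(0, "marker_id", self.scores.index)
        out = pd.concat([out.reset_index(drop=True),
                         self.scores[cols].reset_index(drop=True)], axis=1)
        header = io.StringIO()
        if self.parents:
            header.write(f"#parents\t{self.parents[0]}\t{self.parents[1]}\n")
        if self.f1:
            header.write(f"#f1\t{self.f1}\n")
        with open(path, "w") as fh:
            fh.write(header.getvalue())
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ScoreMatrix":
        parents = None
        f1 = None
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for line in lines:
            if line.startswith("#parents"):
                _, p1, p2 = line.rstrip("\n").split("\t")
                parents = (p1, p2)
            elif line.startswith("#f1"):
                f1 = line.rstrip("\n").split("\t")[1]
            else:
                break
            body_start += 1
        df = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t",
                         dtype={"marker_id": str, "scaffold": str})
        df = df.set_index("marker_id")
        meta = df[META_COLUMNS].copy()
        meta["reversed"] = meta["reversed"].astype(bool)
        scores = df.drop(columns=META_COLUMNS).astype(str)
        return cls(scores, meta, parents, f1)

    def to_vcf(self, path, depth: int = 20) -> None:
        """Emit definite calls (A/H/B) as a minimal text VCF; C/D/U become ./.

        The parent-1 allele is written as REF, the parent-2 allele as ALT,
        with a constant DP so the file round-trips through ``encode_calls``.
        """
        gt_map = {"A": "0/0", "H": "0/1", "B": "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
            cols = list(self.scores.columns)
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(cols) + "\n")
            for mid, meta_row in self.meta.iterrows():
                row = self.scores.loc[mid]
                cells = []
                for c in cols:
                    gt = gt_map.get(row[c], "./.")
                    cells.append(f"{gt}:{depth}")
                fh.write(
                    f"{meta_row['scaffold']}\t{int(meta_row['bp'])}\t{mid}\tG\tA\t.\t.\t"
                    f"QD=25.0\tGT:DP\t" + "\t".join(cells) + "\n"
                )


# ---------------------------------------------------------------------------
# Variant call sets
# ---------------------------------------------------------------------------

@dataclass
class VariantCallSet:
    """Biallelic per-sample calls with depths, keyed by (scaffold, position).

    ``sites`` has one row per variant with columns ``scaffold``, ``bp``,
    ``ref``, ``alt``, ``qd``, ``maf``, ``caller`` and (after merging)
    ``origin``; ``gt`` holds genotype codes per site x sample
    (0 hom-ref, 1 het, 2 hom-alt, -1 missing) and ``dp`` the read depths.
    """

    sites: pd.DataFrame
    gt: np.ndarray
    dp: np.ndarray
    samples: list[str]
    rejected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        key = list(zip(self.sites["scaffold"], self.sites["bp"]))
        if len(set(key)) != len(key):
            raise ConfigError("duplicate (scaffold, bp) keys within a caller set")

    @property
    def keys(self) -> list[tuple]:
        return list(zip(self.sites["scaffold"], self.sites["bp"]))


def read_vcf(path, caller: str = "HC") -> VariantCallSet:
    """Read a (plain-text or bgzipped) VCF into a VariantCallSet.

    Multiallelic records are rejected with a per-record diagnostic.  QD is
    taken from INFO when present; minor-allele frequency is computed from the
    genotypes.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, gts, dps, rejected = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            rejected.append(
                f"{var.CHROM}:{var.POS} rejected: multiallelic ALT={','.join(var.ALT)}"
            )
            continue
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        g = np.asarray(var.gt_types, dtype=np.int8)
        code = np.where(g == 0, 0, np.where(g == 1, 1, np.where(g == 3, 2, -1)))
        dp = var.format("DP")
        dp = (np.zeros(len(samples), dtype=np.int32) if dp is None
              else np.nan_to_num(dp.astype(float).ravel(), nan=0).astype(np.int32))
        alt_n = (code == 2).sum() * 2 + (code == 1).sum()
        tot = (code >= 0).sum() * 2
        af = alt_n / tot if tot else 0.0
        rows.append({
            "scaffold": var.CHROM, "bp": var.POS, "ref": var.REF, "alt": var.ALT[0],
            "qd": float(var.INFO.get("QD", np.nan)), "maf": min(af, 1 - af),
            "caller": caller,
        })
        gts.append(code)
        dps.append(dp)
    sites = pd.DataFrame(rows)
    return VariantCallSet(
        sites,
        np.array(gts, dtype=np.int8).reshape(len(rows), len(samples)),
        np.array(dps, dtype=np.int32).reshape(len(rows), len(samples)),
        samples,
        rejected,
    )


def encode_calls(
    calls: VariantCallSet,
    min_depth: int = 8,
    min_maf: float = 0.05,
    min_qd: float = 10.0,
    parents: tuple[str, str] | None = None,
    f1: str | None = None,
) -> ScoreMatrix:
    """Convert filtered variant calls to mapping scores.

    Sites failing the biallelic/MAF/QD filters are excluded; per-sample
    calls below ``min_depth`` (inclusive threshold: depth >= min_depth is
    kept) or missing become U.
    """
    if min_depth < 1:
        raise ConfigError("min_depth must be >= 1")
    sites = calls.sites
    keep = np.ones(len(sites), dtype=bool)
    maf = sites["maf"].to_numpy(float)
    qd = sites["qd"].to_numpy(float)
    keep &= ~(maf <= min_maf)  # "MAF > 5%"
    keep &= ~(np.nan_to_num(qd, nan=np.inf) <= min_qd)  # "QD > 10"
    gt = calls.gt[keep]
    dp = calls.dp[keep]
    sites = sites.loc[keep].reset_index(drop=True)

    letters = np.array(["A", "H", "B"])
    grid = np.where(
        (gt < 0) | (dp < min_depth), "U", letters[np.clip(gt, 0, 2)]
    )
    marker_ids = [f"{s}_{p}" for s, p in zip(sites["scaffold"], sites["bp"])]
    scores = pd.DataFrame(grid, index=marker_ids, columns=calls.samples)
    meta = pd.DataFrame(
        {
            "scaffold": sites["scaffold"].to_numpy(),
            "bp": sites["bp"].to_numpy(),
            "tag_id": marker_ids,
            "reversed": False,
        },
        index=marker_ids,
    )
    return ScoreMatrix(scores, meta, parents=parents, f1=f1)


def merge_callers(
    set_hc: VariantCallSet,
    set_ug: VariantCallSet,
    precedence: str = "HC",
    conflict_to_missing: bool = False,
) -> VariantCallSet:
    """Union two caller sets by (scaffold, position) into a nonredundant set.

    Shared keys are emitted once with origin "common"; per-sample genotype
    conflicts at shared keys are resolved by ``precedence`` ("HC" or "UG"),
    or set to missing when ``conflict_to_missing``.  Allele mismatches at a
    shared key are flagged and counted but still resolved by precedence.
    """
    if precedence not in ("HC", "UG"):
        raise ConfigError("precedence must be 'HC' or 'UG'")
    if set_hc.samples != set_ug.samples:
        raise ConfigError("caller sets must cover the same samples")
    hc_keys = {k: i for i, k in enumerate(set_hc.keys)}
    ug_keys = {k: i for i, k in enumerate(set_ug.keys)}
    all_keys = sorted(set(hc_keys) | set(ug_keys))

    rows, gts, dps = [], [], []
    n_conflicts = 0
    allele_flags = []
    for key in all_keys:
        in_hc, in_ug = key in hc_keys, key in ug_keys
        if in_hc and in_ug:
            i, j = hc_keys[key], ug_keys[key]
            rh, ru = set_hc.sites.iloc[i], set_ug.sites.iloc[j]
            if (rh["ref"], rh["alt"]) != (ru["ref"], ru["alt"]):
                allele_flags.append(key)
            first, second = ((set_hc, i), (set_ug, j))
            if precedence == "UG":
                first, second = second, first
            g1, g2 = first[0].gt[first[1]], second[0].gt[second[1]]
            conflict = (g1 >= 0) & (g2 >= 0) & (g1 != g2)
            n_conflicts += int(conflict.sum())
            g = np.where(g1 >= 0, g1, g2)
            if conflict_to_missing:
                g = np.where(conflict, -1, g)
            d = np.maximum(first[0].dp[first[1]], second[0].dp[second[1]])
            base = rh if precedence == "HC" else ru
            row = dict(base)
            row["origin"] = "common"
            rows.append(row)
            gts.append(g)
            dps.append(d)
        else:
            src, idx = (set_hc, hc_keys[key]) if in_hc else (set_ug, ug_keys[key])
            row = dict(src.sites.iloc[idx])
            row["origin"] = f"{row['caller']}-only"
            rows.append(row)
            gts.append(src.gt[idx])
            dps.append(src.dp[idx])

    sites = pd.DataFrame(rows).reset_index(drop=True)
    merged = VariantCallSet(
        sites,
        np.vstack(gts).astype(np.int8),
        np.vstack(dps).astype(np.int32),
        list(set_hc.samples),
        rejected=set_hc.rejected + set_ug.rejected,
    )
    merged.sites.attrs["n_conflicts"] = n_conflicts
    merged.sites.attrs["allele_mismatch_keys"] = allele_flags
    merged.sites.attrs["origin_tally"] = sites["origin"].value_counts().to_dict()
    return merged


# ---------------------------------------------------------------------------
# Score-level transformations
# ---------------------------------------------------------------------------

def _consensus_code(codes) -> str:
    """Intersection of compatible genotype sets; empty intersection -> U."""
    sets = [COMPATIBLE[c] for c in codes if c != "U"]
    if not sets:
        return "U"
    inter = frozenset.intersection(*sets)
    if not inter:
        return "U"
    return _SET_TO_CODE[inter]


def consolidate_tags(scores: ScoreMatrix, tag_window_bp: int = 1000) -> ScoreMatrix:
    """Collapse SNPs within a GBS tag (default 1-kb window) to one row.

    Tags are built greedily along each scaffold: a SNP starts a new tag when
    it lies more than ``tag_window_bp`` from the tag's first SNP.  Per
    individual, codes are combined by genotype-set intersection, so a
    definite code absorbs a compatible partial (A with D gives A) and a
    contradiction (A with B) yields U.
    """
    meta = scores.meta.sort_values(["scaffold", "bp"])
    tag_of = {}
    tag_counter = 0
    cur_scaffold, tag_start = None, None
    for mid, row in meta.iterrows():
        if row["scaffold"] != cur_scaffold or row["bp"] - tag_start > tag_window_bp:
            tag_counter += 1
            cur_scaffold, tag_start = row["scaffold"], row["bp"]
        tag_of[mid] = tag_counter

    grid = scores.scores
    out_rows, out_meta = [], []
    order = meta.index
    groups: dict[int, list[str]] = {}
    for mid in order:
        groups.setdefault(tag_of[mid], []).append(mid)
    for tag, mids in sorted(groups.items()):
        block = grid.loc[mids]
        if len(mids) == 1:
            consensus = block.iloc[0]
        else:
            consensus = block.apply(lambda col: _consensus_code(col.to_numpy()), axis=0)
        first = scores.meta.loc[mids[0]]
        tag_id = f"Tag_{tag}"
        out_rows.append(consensus.rename(tag_id))
        out_meta.append(
            {"scaffold": first["scaffold"], "bp": first["bp"],
             "tag_id": tag_id, "reversed": False}
        )
    new_scores = pd.DataFrame(out_rows)
    new_meta = pd.DataFrame(out_meta, index=new_scores.index)
    return ScoreMatrix(new_scores, new_meta, scores.parents, scores.f1)


def _fits_121(row_progeny: pd.Series, min_p: float = 1e-10) -> bool:
    counts = row_progeny.value_counts()
    obs = np.array([counts.get(c, 0) for c in DEFINITE], dtype=float)
    if obs.sum() == 0:
        return False
    return segregation_test(obs, (1, 2, 1)).p_value >= min_p


def reorient_to_cross(
    scores: ScoreMatrix, p1_col: str | None = None, p2_col: str | None = None,
    min_p: float = 1e-10,
) -> ScoreMatrix:
    """Flip A<->B (and C<->D) where the parental calls contradict their role.

    A marker whose P1-role parent is scored B, or whose P2-role parent is
    scored A, and whose progeny fit 1:2:1, has the phase swap applied to
    every column.  Markers with H or missing parents are left for
    :func:`duplicate_phase_unknown`.
    """
    if p1_col is None or p2_col is None:
        if scores.parents is None:
            raise ConfigError("parent columns are required for reorientation")
        p1_col, p2_col = scores.parents
    out = scores.copy()
    prog_cols = out.progeny_columns
    for mid in out.marker_ids:
        p1c = out.scores.at[mid, p1_col]
        p2c = out.scores.at[mid, p2_col]
        if (p1c == "B" or p2c == "A") and _fits_121(out.scores.loc[mid, prog_cols], min_p):
            out.scores.loc[mid] = out.scores.loc[mid].map(PHASE_SWAP)
    return out


def duplicate_phase_unknown(scores: ScoreMatrix) -> ScoreMatrix:
    """Duplicate markers whose parental phase is unknown, flipping one copy.

    Markers with H, a partial code, or missing data in either parent gain an
    "r" twin with A<->B and C<->D swapped in every column, so that both
    linkage phases are represented for grouping.
    """
    ambiguous = {"H", "C", "D", "U"}
    if scores.parents is None:
        raise ConfigError("parent columns are required for phase duplication")
    p1_col, p2_col = scores.parents
    rows, metas = [], []
    for mid in scores.marker_ids:
        row = scores.scores.loc[mid]
        m = scores.meta.loc[mid]
        rows.append(row)
        metas.append((mid, dict(m)))
        if row[p1_col] in ambiguous or row[p2_col] in ambiguous:
            flipped = row.map(PHASE_SWAP)
            rows.append(flipped.rename(mid + "r"))
            m2 = dict(m)
            m2["reversed"] = True
            metas.append((mid + "r", m2))
    new_scores = pd.DataFrame(rows, index=[k for k, _ in metas])
    new_meta = pd.DataFrame([v for _, v in metas], index=new_scores.index)
    return ScoreMatrix(new_scores, new_meta, scores.parents, scores.f1)


def collapse_cosegregating(
    scores: ScoreMatrix,
) -> tuple[ScoreMatrix, dict[str, list[str]]]:
    """Bin markers with identical full score strings; keep one representative.

    Equality is the exact code string across all individuals (including U).
    The representative is the marker with the lowest (scaffold, bp); the
    returned bin map (representative -> all members, itself included) allows
    re-expansion onto the finished map.
    """
    strings = scores.scores.apply(lambda r: "".join(r), axis=1)
    bins: dict[str, list[str]] = {}
    for mid, s in strings.items():
        bins.setdefault(s, []).append(mid)
    reps, bin_map = [], {}
    for s, members in bins.items():
        members_sorted = sorted(
            members, key=lambda m: (scores.meta.at[m, "scaffold"], scores.meta.at[m, "bp"])
        )
        rep = members_sorted[0]
        reps.append(rep)
        bin_map[rep] = members_sorted
    reps = [m for m in scores.marker_ids if m in bin_map]  # preserve input order
    return scores.subset(reps), bin_map


def expand_bins(marker_ids: list[str], bin_map: dict[str, list[str]]) -> list[str]:
    """Inverse of :func:`collapse_cosegregating` for a list of representatives."""
    out = []
    for mid in marker_ids:
        out.extend(bin_map.get(mid, [mid]))
    return out


def filter_matrix(
    scores: ScoreMatrix, max_missing: float = 0.20, min_p: float = 1e-10
) -> tuple[ScoreMatrix, dict[str, list[str]]]:
    """Apply the missing-data and segregation-distortion filters.

    Progeny with a U fraction above ``max_missing`` are dropped first (so a
    bad sample cannot eliminate markers), then markers by missingness across
    the remaining progeny, then markers whose definite counts fail a 1:2:1
    chi-squared test at ``min_p``.  Partial codes are excluded from the test
    counts.  Removal lists are returned for the distorted-region rescue.
    """
    out = scores.copy()
    prog = out.progeny
    miss_frac = (prog == "U").mean(axis=0)
    bad_progeny = list(miss_frac.index[miss_frac > max_missing])
    keep_cols = [c for c in out.scores.columns if c not in bad_progeny]
    if not [c for c in keep_cols if c in out.progeny_columns]:
        raise ConfigError("all progeny removed by the missing-data filter")
    out = ScoreMatrix(out.scores[keep_cols], out.meta, out.parents, out.f1)

    prog = out.progeny
    m_miss = (prog == "U").mean(axis=1)
    bad_missing = list(m_miss.index[m_miss > max_missing])
    keep = [m for m in out.marker_ids if m not in set(bad_missing)]
    out = out.subset(keep)

    bad_distorted = []
    prog = out.progeny
    arr = prog.to_numpy()
    for i, mid in enumerate(out.marker_ids):
        row = arr[i]
        obs = np.array([(row == c).sum() for c in DEFINITE], dtype=float)
        if obs.sum() == 0:
            continue
        if segregation_test(obs, (1, 2, 1)).p_value < min_p:
            bad_distorted.append(mid)
    out = out.subset([m for m in out.marker_ids if m not in set(bad_distorted)])
    removed = {
        "progeny": bad_progeny,
        "markers_missing": bad_missing,
        "markers_distorted": bad_distorted,
    }
    return out, removed


# ---------------------------------------------------------------------------
# Segregation tests
# ---------------------------------------------------------------------------

@dataclass
class SegTestResult:
    counts: np.ndarray
    expected: np.ndarray
    ratio: tuple
    chi2: float
    df: int
    p_value: float


def segregation_test(counts, ratio) -> SegTestResult:
    """Pearson chi-squared goodness-of-fit of counts to an expected ratio.

    ``counts`` are observed class counts (e.g. green/purple, or A/H/B with
    partial codes excluded); ``ratio`` the expected proportions, e.g.
    (1, 3) or (1, 2, 1).  df = classes - 1.
    """
    obs = np.asarray(counts, dtype=float)
    ratio = tuple(ratio)
    if obs.ndim != 1 or len(obs) != len(ratio):
        raise ConfigError("counts and ratio must have the same length")
    if (obs < 0).any():
        raise ConfigError("counts must be non-negative")
    total = obs.sum()
    if total == 0:
        raise ConfigError("zero total count")
    w = np.asarray(ratio, dtype=float)
    if (w <= 0).any():
        raise ConfigError("ratio terms must be positive")
    expected = total * w / w.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return SegTestResult(obs, expected, ratio, chi2, df, p)
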