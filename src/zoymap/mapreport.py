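"""Map-level summary statistics and segregation-distortion scans.

Reproduces the usual per-linkage-group bookkeeping of a published map
table: marker counts, genetic lengths, physical span covered by the mapped
markers (last minus first marker bp), percent coverage of the chromosome,
gap census, plus the genetic-vs-physical length correlation and a
per-marker transmission-ratio-distortion profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genocode import DEFINITE, ScoreMatrix, segregation_test
from .linkage import LinkageMap
from .simdata import load_map_template


@dataclass
class MapSummary:
    per_lg: pd.DataFrame
    totals: dict
    gap_threshold_cm: float

    def as_frame(self) -> pd.DataFrame:
        out = self.per_lg.astype(object)
        out.loc["Total"] = {c: self.totals.get(c) for c in out.columns}
        return out


def _summary_from_perlg(per_lg: pd.DataFrame, gap_threshold_cm: float,
                        n_gaps: int | None) -> MapSummary:
    per_lg = per_lg.copy()
    per_lg["covered_bp"] = per_lg["last_marker_bp"] - per_lg["first_marker_bp"]
    per_lg["pct_coverage"] = 100.0 * per_lg["covered_bp"] / per_lg["length_bp"]
    n_lg = len(per_lg)
    tot_markers = int(per_lg["n_markers"].sum())
    tot_cm = float(per_lg["length_cm"].sum())
    intervals = tot_markers - n_lg
    totals = {
        "n_lg": n_lg,
        "n_markers": tot_markers,
        "length_cm": tot_cm,
        "length_bp": int(per_lg["length_bp"].sum()),
        "covered_bp": int(per_lg["covered_bp"].sum()),
        "avg_markers_per_lg": tot_markers / n_lg,
        "avg_length_cm": tot_cm / n_lg,
        "avg_pct_coverage": float(per_lg["pct_coverage"].mean()),
        "overall_pct_coverage": float(
            100.0 * per_lg["covered_bp"].sum() / per_lg["length_bp"].sum()
        ),
        "mean_marker_spacing_cm": tot_cm / intervals if intervals > 0 else float("nan"),
    }
    if n_gaps is not None:
        totals["n_gaps_ge_threshold"] = n_gaps
    return MapSummary(per_lg, totals, gap_threshold_cm)


def summarize_map(
    lmap: LinkageMap | pd.DataFrame,
    chromosome_lengths_bp: dict[str, int] | pd.Series,
    gap_threshold_cm: float = 5.0,
) -> MapSummary:
    """Per-LG and total map statistics from a built map or a marker table.

    Accepts a :class:`LinkageMap` or its long-format ``marker_table()``
    (columns lg, marker_id, cm, bp).  ``chromosome_lengths_bp`` maps each
    LG to the physical length of its chromosome.  "Covered" is the physical
    span between the first and last mapped marker (0 for singleton LGs);
    the gap census counts adjacent intervals of at least
    ``gap_threshold_cm``.
    """
    table = lmap.marker_table() if isinstance(lmap, LinkageMap) else lmap
    lengths = dict(chromosome_lengths_bp)
    rows = []
    n_gaps = 0
    for lg, sub in table.groupby("lg", sort=False):
        sub = sub.sort_values("cm")
        gaps = np.diff(sub["cm"].to_numpy())
        n_gaps += int((gaps >= gap_threshold_cm).sum())
        bp = sub["bp"].to_numpy()
        rows.append({
            "lg": lg,
            "length_bp": int(lengths[lg]),
            "n_markers": len(sub),
            "length_cm": float(sub["cm"].max() - sub["cm"].min()),
            "first_marker_bp": int(bp.min()) if len(bp) else 0,
            "last_marker_bp": int(bp.max()) if len(bp) else 0,
        })
    per_lg = pd.DataFrame(rows).set_index("lg")
    if per_lg.empty:
        raise ValueError("empty map")
    return _summary_from_perlg(per_lg, gap_threshold_cm, n_gaps)


def summarize_published_table(per_lg: pd.DataFrame | None = None) -> MapSummary:
    """Summary statistics recomputed from printed per-LG columns.

    With no argument the packaged zoysiagrass reference-map table is used
    (columns chromosome, length_bp, n_markers, length_cm, first_marker_bp,
    last_marker_bp).  The gap census needs marker-level data and is omitted.
    """
    if per_lg is None:
        per_lg = load_map_template()
    per_lg = per_lg.rename(columns={"chromosome": "lg"}).set_index("lg")
    return _summary_from_perlg(per_lg, 5.0, None)


def length_correlation(summary: MapSummary) -> dict:
    """Pearson correlation of genetic LG length with physical length.

    Reported against the full chromosome length, the covered span, and the
    full set excluding no LG is ambiguous in published tables, so all
    variants are returned: keys ``chromosome`` and ``covered`` each hold
    (r, r2, p) from a two-sided t-test.
    """
    df = summary.per_lg
    if len(df) < 3:
        raise ValueError("need at least 3 linkage groups")
    out = {}
    for key, col in (("chromosome", "length_bp"), ("covered", "covered_bp")):
        r, p = stats.pearsonr(df["length_cm"], df[col])
        out[key] = {"r": float(r), "r2": float(r * r), "p": float(p)}
    return out


@dataclass
class DistortionProfile:
    per_marker: pd.DataFrame
    regions: pd.DataFrame
    p_threshold: float


def distortion_scan(
    scores: ScoreMatrix,
    map_table: pd.DataFrame | None = None,
    p_threshold: float = 1e-10,
    min_run: int = 1,
) -> DistortionProfile:
    """Per-marker genotype-class frequencies and 1:2:1 distortion flags.

    Partial codes are excluded from the test counts.  When a map table is
    given, markers are ordered along it and contiguous runs of at least
    ``min_run`` markers below ``p_threshold`` are reported as distorted
    regions with the favoured (over-represented) parental allele labelled.
    """
    order = (list(scores.marker_ids) if map_table is None
             else [m for m in map_table.sort_values(["lg", "cm"])["marker_id"]
                   if m in set(scores.marker_ids)])
    lg_of = ({} if map_table is None
             else dict(zip(map_table["marker_id"], map_table["lg"])))
    rows = []
    for mid in order:
        counts = scores.code_counts(mid)
        obs = np.array([counts[c] for c in DEFINITE], dtype=float)
        tot = obs.sum()
        if tot == 0:
            rows.append({"marker_id": mid, "lg": lg_of.get(mid, ""), "n_definite": 0,
                         "freq_A": np.nan, "freq_H": np.nan, "freq_B": np.nan,
                         "p_value": np.nan, "favoured": "", "flagged": False})
            continue
        res = segregation_test(obs, (1, 2, 1))
        flagged = res.p_value < p_threshold
        favoured = ""
        if flagged:
            favoured = "P1" if obs[0] > obs[2] else "P2"
        rows.append({
            "marker_id": mid, "lg": lg_of.get(mid, ""), "n_definite": int(tot),
            "freq_A": obs[0] / tot, "freq_H": obs[1] / tot, "freq_B": obs[2] / tot,
            "p_value": res.p_value, "favoured": favoured, "flagged": flagged,
        })
    per_marker = pd.DataFrame(rows)

    regions = []
    run = []
    def close_run():
        if len(run) >= min_run:
            sub = per_marker.iloc[run]
            fav = sub["favoured"].mode()
            regions.append({
                "lg": sub["lg"].iloc[0],
                "first_marker": sub["marker_id"].iloc[0],
                "last_marker": sub["marker_id"].iloc[-1],
                "n_markers": len(sub),
                "favoured": fav.iloc[0] if not fav.empty else "",
                "min_p": float(sub["p_value"].min()),
            })
    prev_lg = None
    for i, row in per_marker.iterrows():
        if row["flagged"] and (prev_lg is None or row["lg"] == prev_lg or not run):
            run.append(i)
            prev_lg = row["lg"]
        else:
            close_run()
            run = [i] if row["flagged"] else []
            prev_lg = row["lg"] if row["flagged"] else None
    close_run()
    return DistortionProfile(per_marker, pd.DataFrame(regions), p_threshold)
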