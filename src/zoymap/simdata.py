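"""Synthetic interspecific F2 / F1 cross simulator with ground truth.

The generator emulates the statistical structure of a zoysiagrass-style
mapping experiment: two divergent parents (P1, P2) crossed to a single F1,
which is selfed to produce an F2 population (or, alternatively, a family of
F1 siblings).  Meioses follow a no-interference (Poisson/Haldane) crossover
process.  Optional transmission-ratio-distortion loci bias which gametes or
zygotes survive, and a fully linked two-SNP causal gene (see
:mod:`zoymap.inheritance`) drives binary stolon / seed-head phenotypes.

True haplotypes, crossover positions and realized gene diplotypes are
retained in a :class:`SimTruth` object so that parameter-recovery tests can
compare estimates against the generating values.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import genocode, inheritance
from .genocode import ConfigError, ScoreMatrix

P1_NAME, P2_NAME, F1_NAME = "P1", "P2", "F1"


# ---------------------------------------------------------------------------
# Genome specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length_cm: float
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_cm < 0:
            raise ConfigError(f"{self.name}: negative cM length")
        if self.length_bp <= 0:
            raise ConfigError(f"{self.name}: bp length must be positive")


@dataclass
class GenomeSpec:
    """Chromosome lengths plus per-chromosome marker positions (cM and bp)."""

    chromosomes: list[ChromosomeSpec]
    marker_cm: dict[str, np.ndarray]
    marker_bp: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ConfigError("empty genome")
        for ch in self.chromosomes:
            cm = np.asarray(self.marker_cm[ch.name], dtype=float)
            bp = np.asarray(self.marker_bp[ch.name], dtype=np.int64)
            if len(cm) != len(bp):
                raise ConfigError(f"{ch.name}: cM and bp marker arrays differ in length")
            if len(cm) and (cm.min() < 0 or cm.max() > ch.length_cm + 1e-9):
                raise ConfigError(f"{ch.name}: marker cM positions outside [0, length]")
            if np.any(np.diff(cm) < 0):
                raise ConfigError(f"{ch.name}: marker cM positions must be sorted")
            if np.any(np.diff(bp) <= 0):
                raise ConfigError(f"{ch.name}: marker bp positions must be strictly sorted")
            self.marker_cm[ch.name] = cm
            self.marker_bp[ch.name] = bp

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def total_cm(self) -> float:
        return sum(c.length_cm for c in self.chromosomes)

    def n_markers(self, name: str | None = None) -> int:
        if name is not None:
            return len(self.marker_cm[name])
        return sum(len(v) for v in self.marker_cm.values())

    def marker_table(self) -> pd.DataFrame:
        """Long-format marker table (lg, marker_id, cm, scaffold, bp)."""
        rows = []
        for ch in self.chromosomes:
            for i, (cm, bp) in enumerate(
                zip(self.marker_cm[ch.name], self.marker_bp[ch.name])
            ):
                rows.append(
                    {"lg": ch.name, "marker_id": _marker_id(ch.name, i),
                     "cm": float(cm), "scaffold": ch.name, "bp": int(bp)}
                )
        return pd.DataFrame(rows)

    # -- constructors -----------------------------------------------------
    @classmethod
    def uniform(cls, lengths_cm, spacing_cm: float = 1.0,
                bp_per_cm: float = 150_000.0) -> "GenomeSpec":
        """Ad-hoc genome: chromosomes of the given cM lengths, evenly spaced
        markers, and physical positions proportional to cM."""
        chroms, cm_d, bp_d = [], {}, {}
        for i, L in enumerate(lengths_cm):
            name = f"chr{i + 1:02d}"
            length_bp = max(int(round(max(L, 1.0) * bp_per_cm)), 1000)
            chroms.append(ChromosomeSpec(name, float(L), length_bp))
            if L == 0:
                cm = np.zeros(3)
            else:
                cm = np.arange(0.0, L + 1e-9, spacing_cm)
            bp_d[name] = _interp_bp(cm, L, length_bp)
            cm_d[name] = cm
        return cls(chroms, cm_d, bp_d)

    @classmethod
    def default(cls, spacing_cm: float = 1.0,
                template_marker_counts: bool = False) -> "GenomeSpec":
        """The 20-chromosome zoysiagrass template.

        Chromosome cM and bp lengths follow the packaged map-statistics
        table.  Markers are evenly spaced every ``spacing_cm``; with
        ``template_marker_counts`` the per-chromosome marker numbers of the
        template (8402 in total) are used instead, matching the density of
        the real map.
        """
        tbl = load_map_template()
        chroms, cm_d, bp_d = [], {}, {}
        for _, row in tbl.iterrows():
            name = f"chr{int(row['chromosome']):02d}"
            L = float(row["length_cm"])
            chroms.append(ChromosomeSpec(name, L, int(row["length_bp"])))
            if template_marker_counts:
                cm = np.linspace(0.0, L, int(row["n_markers"]))
            else:
                cm = np.arange(0.0, L + 1e-9, spacing_cm)
            cm_d[name] = cm
            bp_d[name] = _interp_bp(cm, L, int(row["length_bp"]))
        return cls(chroms, cm_d, bp_d)


def load_map_template() -> pd.DataFrame:
    """Published per-chromosome map statistics used as the genome template."""
    ref = importlib.resources.files("zoymap.data") / "zoysia_f2_map_stats.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def _marker_id(chrom: str, i: int) -> str:
    return f"{chrom}_M{i + 1:04d}"


def _interp_bp(cm: np.ndarray, length_cm: float, length_bp: int) -> np.ndarray:
    if len(cm) == 0:
        return np.array([], dtype=np.int64)
    frac = cm / length_cm if length_cm > 0 else np.linspace(0, 1, len(cm))
    bp = np.round(1 + frac * (length_bp - 1)).astype(np.int64)
    # enforce strict monotonicity after rounding
    for i in range(1, len(bp)):
        if bp[i] <= bp[i - 1]:
            bp[i] = bp[i - 1] + 1
    return bp


# ---------------------------------------------------------------------------
# Observation and distortion models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObservationModel:
    """How true genotypes turn into observed mapping scores.

    Depths are negative-binomial with the given mean and dispersion (shape);
    cells below ``min_depth`` are scored U.  ``error_rate`` is the chance a
    definite genotype is miscoded as one of the two other definite codes;
    ``partial_code_rate`` the chance a call degrades to a partial code
    (H becomes C or D, B becomes C, A becomes D); ``missing_rate`` an extra
    chance of U regardless of depth.
    """

    min_depth: int = 8
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0
    error_rate: float = 0.005
    partial_code_rate: float = 0.02
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ConfigError("min_depth must be >= 1")
        for name in ("error_rate", "partial_code_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ConfigError("depth parameters must be positive")


PERFECT_OBSERVATION = ObservationModel(
    min_depth=1, depth_mean=100.0, depth_dispersion=1e6,
    error_rate=0.0, partial_code_rate=0.0, missing_rate=0.0,
)


@dataclass(frozen=True)
class DistortionSpec:
    """A transmission-ratio-distortion locus.

    ``k`` is the transmission probability of the favoured allele per gamete
    (0.5 none, 1.0 complete).  ``stage`` selects the mechanism: "gametic"
    rejects gametes carrying the disfavoured allele at the locus (e.g. a
    killer-target drive destroying gametes), "zygotic" removes disfavoured
    homozygous zygotes with the analogous survival probability, which at
    k = 1 leaves the 1 hom : 2 het pattern seen at completely distorted
    loci.  ``favoured`` names the parent whose allele is driven.
    """

    chromosome: str
    position_cm: float
    k: float
    stage: str = "gametic"
    favoured: str = P1_NAME

    def __post_init__(self) -> None:
        if not 0.5 <= self.k <= 1.0:
            raise ConfigError("k must lie in [0.5, 1.0]")
        if self.stage not in ("gametic", "zygotic"):
            raise ConfigError("stage must be 'gametic' or 'zygotic'")
        if self.favoured not in (P1_NAME, P2_NAME):
            raise ConfigError(f"favoured must be {P1_NAME!r} or {P2_NAME!r}")

    @property
    def favoured_index(self) -> int:
        return 0 if self.favoured == P1_NAME else 1

    @property
    def survival(self) -> float:
        """Acceptance probability of a disfavoured carrier, (1 - k) / k."""
        return (1.0 - self.k) / self.k


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class Gamete:
    """One meiotic product: a mosaic over the transmitting parent's homologs."""

    start: int                 # homolog carried at position 0
    crossovers: np.ndarray     # sorted cM positions

    def ancestry_at(self, pos_cm) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(pos_cm, dtype=float))
        return (self.start + np.searchsorted(self.crossovers, pos)) % 2


@dataclass
class SimTruth:
    """Ground truth of a simulated cross.

    ``gametes[chrom][i]`` holds the (copy-0, copy-1) gametes of individual
    ``i``; ``ancestry[chrom]`` the (n, 2, n_markers) homolog-origin array at
    the marker positions.  For the F2 design homolog 0 of the F1 is the
    P1-derived chromosome, so ancestry doubles as founder origin.
    """

    genome: GenomeSpec
    design: str
    n_progeny: int
    gametes: dict[str, list[tuple[Gamete, Gamete]]]
    ancestry: dict[str, np.ndarray]
    distortions: tuple[DistortionSpec, ...] = ()
    seed: int | None = None

    @property
    def individuals(self) -> list[str]:
        prefix = "F2" if self.design == "f2" else "F1fam"
        return [f"{prefix}_{i + 1:04d}" for i in range(self.n_progeny)]

    def genotypes(self, chrom: str) -> np.ndarray:
        """(n, n_markers) genotype codes 0=AA, 1=AB, 2=BB by founder origin.

        For the F1-family design every marker is heterozygous (the founders
        are modelled as fully homozygous), which is returned as all-1.
        """
        anc = self.ancestry[chrom]
        if self.design == "f2":
            return anc.sum(axis=1).astype(np.int8)
        return np.ones((anc.shape[0], anc.shape[2]), dtype=np.int8)

    def ancestry_at(self, chrom: str, pos_cm: float) -> np.ndarray:
        """(n, 2) homolog origin of each chromosome copy at an arbitrary cM."""
        out = np.empty((self.n_progeny, 2), dtype=np.int8)
        for i, (g0, g1) in enumerate(self.gametes[chrom]):
            out[i, 0] = g0.ancestry_at(pos_cm)[0]
            out[i, 1] = g1.ancestry_at(pos_cm)[0]
        return out

    def crossover_counts(self) -> pd.DataFrame:
        rows = []
        for chrom, gams in self.gametes.items():
            for i, (g0, g1) in enumerate(gams):
                rows.append({"chromosome": chrom, "individual": i,
                             "n_crossovers": len(g0.crossovers) + len(g1.crossovers)})
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "design": self.design,
            "n_progeny": self.n_progeny,
            "seed": self.seed,
            "chromosomes": [
                {"name": c.name, "length_cm": c.length_cm, "length_bp": int(c.length_bp)}
                for c in self.genome.chromosomes
            ],
            "crossovers": {
                chrom: [
                    [[int(g.start), list(map(float, g.crossovers))] for g in pair]
                    for pair in gams
                ]
                for chrom, gams in self.gametes.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _draw_gamete(rng, length_cm: float, marker_cm: np.ndarray,
                 gametic: list[DistortionSpec]) -> Gamete:
    """One meiosis under the no-interference model, with gametic rejection."""
    while True:
        n_xo = rng.poisson(length_cm / 100.0)
        xos = np.sort(rng.uniform(0.0, length_cm, n_xo)) if n_xo else np.empty(0)
        start = int(rng.integers(2))
        g = Gamete(start, xos)
        ok = True
        for d in gametic:
            allele = g.ancestry_at(d.position_cm)[0]
            if allele != d.favoured_index and rng.random() >= d.survival:
                ok = False
                break
        if ok:
            return g


def simulate_cross(
    genome: GenomeSpec,
    n_progeny: int = 530,
    design: str = "f2",
    distortions: tuple[DistortionSpec, ...] = (),
    seed: int = 0,
) -> SimTruth:
    """Simulate an F2 (selfed-F1) or F1-family population.

    Each gamete is an independent no-interference meiosis: the crossover
    count is Poisson with mean equal to the chromosome length in Morgans and
    positions are uniform.  Gametic distortion rejects gametes carrying the
    disfavoured allele at the driver locus with probability 1 - (1-k)/k;
    zygotic distortion applies the same survival to disfavoured homozygous
    zygotes.  With a fixed seed the output is bit-identical across runs.
    """
    if n_progeny < 1:
        raise ConfigError("n_progeny must be >= 1")
    if design not in ("f2", "f1"):
        raise ConfigError("design must be 'f2' or 'f1'")
    names = set(genome.names)
    for d in distortions:
        if d.chromosome not in names:
            raise ConfigError(f"distortion locus on unknown chromosome {d.chromosome}")
        ch = next(c for c in genome.chromosomes if c.name == d.chromosome)
        if not 0 <= d.position_cm <= ch.length_cm:
            raise ConfigError("distortion locus outside chromosome bounds")
    rng = np.random.default_rng(seed)

    gametes: dict[str, list[tuple[Gamete, Gamete]]] = {c: [] for c in genome.names}
    by_chrom_gametic = {
        c: [d for d in distortions if d.chromosome == c and d.stage == "gametic"]
        for c in genome.names
    }
    by_chrom_zygotic = {
        c: [d for d in distortions if d.chromosome == c and d.stage == "zygotic"]
        for c in genome.names
    }

    for ch in genome.chromosomes:
        gam_d = by_chrom_gametic[ch.name]
        zyg_d = by_chrom_zygotic[ch.name]
        pairs = []
        while len(pairs) < n_progeny:
            g0 = _draw_gamete(rng, ch.length_cm, genome.marker_cm[ch.name], gam_d)
            g1 = _draw_gamete(rng, ch.length_cm, genome.marker_cm[ch.name], gam_d)
            ok = True
            if design == "f2":
                for d in zyg_d:
                    a = (g0.ancestry_at(d.position_cm)[0], g1.ancestry_at(d.position_cm)[0])
                    disfav = 1 - d.favoured_index
                    if a == (disfav, disfav) and rng.random() >= d.survival:
                        ok = False
                        break
            if ok:
                pairs.append((g0, g1))
        gametes[ch.name] = pairs

    ancestry = {}
    for ch in genome.chromosomes:
        cm = genome.marker_cm[ch.name]
        arr = np.empty((n_progeny, 2, len(cm)), dtype=np.int8)
        for i, (g0, g1) in enumerate(gametes[ch.name]):
            arr[i, 0] = g0.ancestry_at(cm)
            arr[i, 1] = g1.ancestry_at(cm)
        ancestry[ch.name] = arr
    return SimTruth(genome, design, n_progeny, gametes, ancestry,
                    tuple(distortions), seed)


# ---------------------------------------------------------------------------
# Observation: truth -> ScoreMatrix
# ---------------------------------------------------------------------------

_LETTERS = np.array(["A", "H", "B"])
_WRONG = {0: ("H", "B"), 1: ("A", "B"), 2: ("A", "H")}


def observe_genotypes(truth: SimTruth, model: ObservationModel | None = None,
                      seed: int = 0) -> ScoreMatrix:
    """Corrupt true genotypes into an observed ScoreMatrix.

    Columns are the two parents, the F1, then the progeny.  Corruption order:
    miscoding error, partial-code degradation, depth threshold, extra
    missingness.  With all rates zero and min_depth satisfied the codes equal
    the true genotypes exactly.
    """
    model = model or ObservationModel()
    rng = np.random.default_rng(seed)
    ind = truth.individuals
    columns = [P1_NAME, P2_NAME, F1_NAME] + ind

    blocks, meta_rows, marker_ids = [], [], []
    for ch in truth.genome.chromosomes:
        cm = truth.genome.marker_cm[ch.name]
        bp = truth.genome.marker_bp[ch.name]
        m = len(cm)
        if m == 0:
            continue
        prog_g = truth.genotypes(ch.name)            # (n, m)
        p1 = np.zeros((1, m), dtype=np.int8)
        p2 = np.full((1, m), 2, dtype=np.int8)
        f1 = np.ones((1, m), dtype=np.int8)
        G = np.vstack([p1, p2, f1, prog_g]).T        # (m, n+3)
        blocks.append(G)
        for i in range(m):
            mid = _marker_id(ch.name, i)
            marker_ids.append(mid)
            meta_rows.append({"scaffold": ch.name, "bp": int(bp[i]),
                              "tag_id": mid, "reversed": False})
    G = np.vstack(blocks)                             # (M, N)
    M, N = G.shape

    codes = _LETTERS[G].astype("<U1")
    if model.error_rate > 0:
        err = rng.random((M, N)) < model.error_rate
        which = rng.integers(2, size=(M, N))
        for g in (0, 1, 2):
            for w in (0, 1):
                mask = err & (G == g) & (which == w)
                codes[mask] = _WRONG[g][w]
    if model.partial_code_rate > 0:
        part = rng.random((M, N)) < model.partial_code_rate
        half = rng.integers(2, size=(M, N)).astype(bool)
        codes[part & (codes == "A")] = "D"
        codes[part & (codes == "B")] = "C"
        h = part & (codes == "H")
        codes[h & half] = "C"
        codes[h & ~half] = "D"
    p_nb = model.depth_dispersion / (model.depth_dispersion + model.depth_mean)
    depth = rng.negative_binomial(model.depth_dispersion, p_nb, size=(M, N))
    codes[depth < model.min_depth] = "U"
    if model.missing_rate > 0:
        codes[rng.random((M, N)) < model.missing_rate] = "U"

    scores = pd.DataFrame(codes, index=marker_ids, columns=columns)
    meta = pd.DataFrame(meta_rows, index=marker_ids)
    return ScoreMatrix(scores, meta, parents=(P1_NAME, P2_NAME), f1=F1_NAME)


# ---------------------------------------------------------------------------
# Phenotypes from a placed causal gene
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    truth: SimTruth,
    gene_chromosome: str,
    gene_cm: float,
    f1_diplotype: tuple = (("G", "G"), ("G", "A")),
    p1_diplotype: tuple = (("G", "G"), ("G", "A")),
    p2_diplotype: tuple = (("G", "G"), ("T", "G")),
    misclassification_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[inheritance.GeneDiplotype]]:
    """Binary stolon / seed-head phenotypes from a fully linked two-SNP gene.

    The gene sits at ``gene_cm`` on ``gene_chromosome``; its two SNPs are
    fully linked.  Haplotype tuples are (allele_632, allele_917) ordered by
    homolog: for the F2 design, ``f1_diplotype`` is (P1-derived haplotype,
    P2-derived haplotype) of the selfed F1; for the F1-family design,
    ``p1_diplotype`` / ``p2_diplotype`` give each parent's phased pair.
    Defaults are the Meyer x PI 231146 accessions' phases.  Phenotypes are
    the deterministic penetrance rules, then each tissue call is flipped
    independently with ``misclassification_rate``.  Coding: green = 1,
    purple = 2.
    """
    if gene_chromosome not in truth.genome.names:
        raise ConfigError(f"gene placed off-chromosome: {gene_chromosome}")
    ch = next(c for c in truth.genome.chromosomes if c.name == gene_chromosome)
    if not 0 <= gene_cm <= ch.length_cm:
        raise ConfigError("gene cM position outside chromosome bounds")
    if not 0 <= misclassification_rate <= 1:
        raise ConfigError("misclassification_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    anc = truth.ancestry_at(gene_chromosome, gene_cm)     # (n, 2)
    if truth.design == "f2":
        haps = tuple(inheritance.GeneHaplotype(*h) for h in f1_diplotype)
        source = (haps, haps)
    else:
        source = (
            tuple(inheritance.GeneHaplotype(*h) for h in p1_diplotype),
            tuple(inheritance.GeneHaplotype(*h) for h in p2_diplotype),
        )

    rows, diplotypes = [], []
    for i, name in enumerate(truth.individuals):
        d = inheritance.GeneDiplotype(source[0][anc[i, 0]], source[1][anc[i, 1]])
        diplotypes.append(d)
        ph = inheritance.phenotype_from_diplotype(d)
        stolon, seed_head = ph.coded()
        if misclassification_rate > 0:
            if rng.random() < misclassification_rate:
                stolon = 3 - stolon
            if rng.random() < misclassification_rate:
                seed_head = 3 - seed_head
        rows.append({"individual": name, "stolon": stolon, "seed_head": seed_head})
    return pd.DataFrame(rows).set_index("individual"), diplotypes


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
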