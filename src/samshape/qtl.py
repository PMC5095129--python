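"""Single-QTL genome scanning for an advanced maize×teosinte backcross (BC2S3).

The population is W22 (maize, recurrent parent, allele A) × teosinte (donor,
allele B) after two backcrosses to W22 and three generations of selfing.  The
breeding design fixes the single-locus genotype prior:

* after two backcrosses P(AB) = 1/4 (and P(AA) = 3/4, P(BB) = 0);
* each selfing halves the heterozygote class, so three selfings keep a
  heterozygote with probability (1/2)³ = 1/8 → P(AB) = 1/32 = 2/64;
* the lost heterozygosity splits equally, adding 7/64 to each homozygote →
  P(BB) = 7/64, P(AA) = 48/64 + 7/64 = 55/64.

Genotype probabilities at markers and pseudomarkers come from a hidden Markov
model over {AA, AB, BB} whose transition matrices are computed *exactly* from
the pedigree: the joint two-locus diplotype distribution is propagated through
F1 → BC1 → BC2 → S1 → S2 → S3 for the interval's recombination fraction
(Kosambi inverse of the cM gap), and the genotype-level conditional
P(G_right | G_left) is read off.  Intervals are treated independently (no
crossover interference beyond the map function), which keeps forward–backward
exact under the model.

The scan is Haley–Knott regression of the phenotype on the expected teosinte
allele dosage, LOD = (n/2)·log10(RSS₀/RSS₁); genome-wide significance comes
from phenotype permutations and QTL location from 10^LOD-proportional Bayes
credible intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "CrossPopulation",
    "QtlScanResult",
    "BayesInterval",
    "kosambi_to_cm",
    "kosambi_to_recfrac",
    "bc2s3_priors",
    "bc2s3_joint",
    "bc2s3_transitions",
    "GenotypeProbabilities",
    "genotype_expectations",
    "scanone_hk",
    "permutation_threshold",
    "bayes_interval",
]

# genotype codes in all matrices
AA, AB, BB = 0, 1, 2
MISSING = -1

GENO_LETTERS = {AA: "A", AB: "H", BB: "B", MISSING: "-"}
LETTER_GENO = {"A": AA, "H": AB, "B": BB, "-": MISSING}


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi_to_cm(rec_fraction):
    """Kosambi map distance d = 25·ln((1+2r)/(1−2r)) in cM for 0 ≤ r < 0.5."""
    r = np.asarray(rec_fraction, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must satisfy 0 <= r < 0.5")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if np.isscalar(rec_fraction) else d


def kosambi_to_recfrac(d):
    """Inverse Kosambi: r = tanh(d/50)/2 for map distance d ≥ 0 in cM."""
    dd = np.asarray(d, dtype=float)
    if np.any(dd < 0):
        raise ValueError("map distance must be >= 0")
    r = 0.5 * np.tanh(dd / 50.0)
    return float(r) if np.isscalar(d) else r


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Marker positions (cM, Kosambi) on named chromosomes."""

    chromosomes: list[str]
    marker_names: dict[str, list[str]]
    positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ch in self.chromosomes:
            pos = np.asarray(self.positions[ch], dtype=float)
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions on chromosome {ch} must be non-decreasing")
            self.positions[ch] = pos
            names = self.marker_names[ch]
            if len(names) != pos.size:
                raise ValueError(f"chromosome {ch}: {len(names)} names vs {pos.size} positions")
            dup = seen.intersection(names)
            if dup:
                raise ValueError(f"duplicate marker names: {sorted(dup)}")
            seen.update(names)

    @property
    def n_markers(self) -> int:
        return sum(len(v) for v in self.marker_names.values())

    def marker_index(self) -> dict[str, int]:
        """Marker name -> column index in the genome-wide genotype matrix."""
        idx = {}
        i = 0
        for ch in self.chromosomes:
            for name in self.marker_names[ch]:
                idx[name] = i
                i += 1
        return idx


@dataclass
class CrossPopulation:
    """A BC2S3 cross: genetic map, genotype matrix and per-line phenotypes.

    ``genotypes`` is (n_lines, n_markers) int8 with 0=AA, 1=AB, 2=BB, -1
    missing, columns ordered chromosome-by-chromosome as in the map.
    ``phenotypes`` is a DataFrame indexed by line_id, one column per trait.
    ``replicated_phenotypes`` (optional) holds the raw per-replicate table
    (columns line_id, replicate, then traits) before BLUP summarisation.
    """

    map: GeneticMap
    genotypes: np.ndarray
    phenotypes: pd.DataFrame
    cross_design: tuple[int, int] = (2, 3)  # (n_backcross, n_self)
    replicated_phenotypes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.shape != (len(self.phenotypes), self.map.n_markers):
            raise ValueError(
                f"genotype matrix {g.shape} does not match "
                f"{len(self.phenotypes)} lines x {self.map.n_markers} markers"
            )
        self.genotypes = g

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def line_ids(self) -> list[str]:
        return [str(i) for i in self.phenotypes.index]


@dataclass
class BayesInterval:
    """Bayes credible interval for QTL location on one chromosome."""

    chromosome: str
    lower: float
    peak: float
    upper: float
    coverage: float = 0.95

    def __post_init__(self) -> None:
        if not self.lower <= self.peak <= self.upper:
            raise ValueError("require lower <= peak <= upper")


@dataclass
class QtlScanResult:
    """LOD curve over the (pseudo)marker grid with optional threshold/intervals.

    ``table`` columns: chr, pos_cM, marker (grid-point name), lod, is_marker.
    """

    table: pd.DataFrame
    trait: str
    threshold: float | None = None
    alpha: float | None = None
    n_permutations: int = 0
    intervals: list[BayesInterval] = field(default_factory=list)

    def max_lod(self) -> float:
        return float(self.table["lod"].max())

    def peak(self) -> tuple[str, float]:
        """(chromosome, position) of the genome-wide LOD maximum."""
        row = self.table.loc[self.table["lod"].idxmax()]
        return str(row["chr"]), float(row["pos_cM"])


# ---------------------------------------------------------------------------
# exact BC2S3 two-locus genotype distribution
# ---------------------------------------------------------------------------
# Haplotypes over two loci are coded 0..3 as 2*a1 + a2 with allele a in
# {0=A, 1=B}; a diplotype is an ordered haplotype pair.  The distribution over
# the 16 diplotypes is propagated generation by generation; vectorised over an
# array of recombination fractions.

_H = np.arange(4)
_A1 = _H >> 1  # allele at locus 1
_A2 = _H & 1  # allele at locus 2


def _gamete_tensors() -> tuple[np.ndarray, np.ndarray]:
    """(T0, T1) with P(gamete g | diplotype (h1,h2); r) = T0[h1,h2,g] + r*T1[h1,h2,g]."""
    T0 = np.zeros((4, 4, 4))
    T1 = np.zeros((4, 4, 4))
    for h1 in range(4):
        for h2 in range(4):
            rec1 = 2 * _A1[h1] + _A2[h2]  # locus1 from h1, locus2 from h2
            rec2 = 2 * _A1[h2] + _A2[h1]
            # parental gametes, prob (1-r)/2 each
            T0[h1, h2, h1] += 0.5
            T0[h1, h2, h2] += 0.5
            T1[h1, h2, h1] -= 0.5
            T1[h1, h2, h2] -= 0.5
            # recombinant gametes, prob r/2 each
            T1[h1, h2, rec1] += 0.5
            T1[h1, h2, rec2] += 0.5
    return T0, T1


_T0, _T1 = _gamete_tensors()


def bc2s3_priors() -> np.ndarray:
    """Single-locus genotype prior (AA, AB, BB) = (55, 2, 7)/64 for BC2S3."""
    return np.array([55.0, 2.0, 7.0]) / 64.0


def bc2s3_joint(rec_fraction) -> np.ndarray:
    """Exact joint two-locus genotype distribution P(G_left, G_right) for BC2S3.

    ``rec_fraction`` may be a scalar or an array of shape (K,); the result has
    shape (3, 3) or (K, 3, 3).  Computed by propagating the diplotype
    distribution through F1 → 2 backcrosses → 3 selfings.
    """
    r = np.atleast_1d(np.asarray(rec_fraction, dtype=float))
    K = r.size
    Pg = _T0[None] + r[:, None, None, None] * _T1  # (K, 4, 4, 4)

    # F1: haplotypes (A,A) x (B,B)
    p = np.zeros((K, 4, 4))
    p[:, 0, 3] = 1.0
    for _ in range(2):  # backcrosses to the AA parent
        gam = np.einsum("kab,kabg->kg", p, Pg)
        p = np.zeros((K, 4, 4))
        p[:, :, 0] = gam
    for _ in range(3):  # selfings: two iid gametes from the same parent
        p = np.einsum("kab,kabg,kabh->kgh", p, Pg, Pg)

    # collapse diplotypes to genotype pairs (count of B alleles per locus)
    g1 = _A1[:, None] + _A1[None, :]  # (4, 4)
    g2 = _A2[:, None] + _A2[None, :]
    joint = np.zeros((K, 3, 3))
    np.add.at(joint, (slice(None), g1, g2), p)
    return joint[0] if np.isscalar(rec_fraction) else joint


def bc2s3_transitions(rec_fraction) -> np.ndarray:
    """HMM transition matrices P(G_right | G_left) for BC2S3, shape (K, 3, 3)."""
    joint = np.atleast_3d(bc2s3_joint(np.atleast_1d(rec_fraction)))
    marg = joint.sum(axis=2, keepdims=True)
    return joint / marg


# ---------------------------------------------------------------------------
# genotype probabilities (forward-backward)
# ---------------------------------------------------------------------------

@dataclass
class GenotypeProbabilities:
    """Posterior genotype probabilities on a (pseudo)marker grid.

    Per chromosome: grid positions (cM), grid-point names, a boolean
    is_marker flag and a (n_lines, n_grid, 3) posterior array.
    """

    chromosomes: list[str]
    grid_cm: dict[str, np.ndarray]
    grid_names: dict[str, list[str]]
    is_marker: dict[str, np.ndarray]
    probs: dict[str, np.ndarray]
    step: float
    error_prob: float

    def dosage(self, chromosome: str) -> np.ndarray:
        """E[teosinte allele dosage]/2 ∈ [0, 1], shape (n_lines, n_grid)."""
        p = self.probs[chromosome]
        return (p[:, :, AB] + 2.0 * p[:, :, BB]) / 2.0

    def stacked_dosage(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Genome-wide dosage matrix and the matching grid table."""
        mats, rows = [], []
        for ch in self.chromosomes:
            mats.append(self.dosage(ch))
            for name, pos, ism in zip(
                self.grid_names[ch], self.grid_cm[ch], self.is_marker[ch]
            ):
                rows.append((ch, pos, name, bool(ism)))
        grid = pd.DataFrame(rows, columns=["chr", "pos_cM", "marker", "is_marker"])
        return np.concatenate(mats, axis=1), grid


def _chromosome_grid(pos: np.ndarray, names: list[str], ch: str, step: float):
    """Union of marker positions and a regular step grid, with names and flags."""
    if step <= 0:
        raise ValueError("step must be > 0")
    lo, hi = float(pos.min()), float(pos.max())
    regular = np.arange(lo, hi + 1e-9, step)
    grid = np.union1d(np.round(pos, 9), np.round(regular, 9))
    is_marker = np.isin(grid, np.round(pos, 9))
    # marker index for each grid point that is a marker (first marker at a position wins)
    name_at = {}
    marker_col = {}
    for j, p in enumerate(np.round(pos, 9)):
        name_at.setdefault(p, names[j])
        marker_col.setdefault(p, j)
    grid_names, marker_cols = [], []
    for g in grid:
        if g in name_at:
            grid_names.append(name_at[g])
            marker_cols.append(marker_col[g])
        else:
            grid_names.append(f"c{ch}.loc{g:g}")
            marker_cols.append(-1)
    return grid, grid_names, is_marker, np.array(marker_cols)


def genotype_expectations(
    cross: CrossPopulation,
    step: float = 1.0,
    error_prob: float = 0.002,
) -> GenotypeProbabilities:
    """Posterior genotype probabilities at markers and pseudomarkers.

    Scaled forward–backward over {AA, AB, BB} per chromosome, vectorised over
    lines.  Emissions: observed genotype with genotyping-error rate
    ``error_prob`` (P(obs = true) = 1 − ε, ε/2 each other class); missing
    genotypes and pseudomarkers are uninformative.  The stationary BC2S3
    prior initialises the chain.
    """
    prior = bc2s3_priors()
    chromosomes, grid_cm, grid_names_d, is_marker_d, probs_d = [], {}, {}, {}, {}
    idx = cross.map.marker_index()
    n = cross.n_lines

    for ch in cross.map.chromosomes:
        names = cross.map.marker_names[ch]
        pos = cross.map.positions[ch]
        if len(names) == 0:
            warnings.warn(f"chromosome {ch} has no markers; skipped", stacklevel=2)
            continue
        cols = [idx[m] for m in names]
        obs = cross.genotypes[:, cols]  # (n, M)

        grid, gnames, ismark, marker_cols = _chromosome_grid(pos, names, ch, step)
        P = grid.size

        # emission probabilities (n, P, 3)
        emis = np.ones((n, P, 3))
        eps = error_prob
        obs_on_grid = np.full((n, P), MISSING, dtype=np.int8)
        obs_on_grid[:, marker_cols >= 0] = obs[:, marker_cols[marker_cols >= 0]]
        observed = obs_on_grid >= 0
        for g in (AA, AB, BB):
            sel = observed & (obs_on_grid == g)
            block = np.full(3, eps / 2.0)
            block[g] = 1.0 - eps
            emis[sel] = block

        # transitions per interval
        gaps = np.diff(grid)
        T = bc2s3_transitions(kosambi_to_recfrac(gaps)) if gaps.size else np.zeros((0, 3, 3))

        # scaled forward
        alpha = np.empty((n, P, 3))
        a = prior[None, :] * emis[:, 0]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, 0] = a
        for j in range(1, P):
            a = (a @ T[j - 1]) * emis[:, j]
            a /= a.sum(axis=1, keepdims=True)
            alpha[:, j] = a
        # backward
        b = np.ones((n, 3))
        post = np.empty((n, P, 3))
        post[:, P - 1] = alpha[:, P - 1]
        for j in range(P - 2, -1, -1):
            b = (emis[:, j + 1] * b) @ T[j].T
            b /= b.sum(axis=1, keepdims=True)
            p = alpha[:, j] * b
            post[:, j] = p / p.sum(axis=1, keepdims=True)

        chromosomes.append(ch)
        grid_cm[ch] = grid
        grid_names_d[ch] = gnames
        is_marker_d[ch] = ismark
        probs_d[ch] = post

    return GenotypeProbabilities(
        chromosomes=chromosomes,
        grid_cm=grid_cm,
        grid_names=grid_names_d,
        is_marker=is_marker_d,
        probs=probs_d,
        step=step,
        error_prob=error_prob,
    )


# ---------------------------------------------------------------------------
# Haley-Knott scan
# ---------------------------------------------------------------------------

_LOD_RSS_FLOOR = 1e-12  # RSS1 floored at this fraction of RSS0 to cap the LOD


def _lod_curve(Xc: np.ndarray, sxx: np.ndarray, yc: np.ndarray, rss0: float, n: int):
    """Vectorised Haley-Knott LOD over all grid positions for one phenotype."""
    sxy = Xc.T @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        rss1 = rss0 - sxy**2 / sxx
    rss1 = np.where(sxx <= 0, rss0, rss1)
    rss1 = np.maximum(rss1, _LOD_RSS_FLOOR * rss0)
    return (n / 2.0) * np.log10(rss0 / rss1)


def _prepare_scan(cross, trait, step, error_prob, probs):
    if trait not in cross.phenotypes.columns:
        raise ValueError(f"trait {trait!r} not in phenotype table")
    if probs is None:
        probs = genotype_expectations(cross, step=step, error_prob=error_prob)
    X, grid = probs.stacked_dosage()
    y = cross.phenotypes[trait].to_numpy(dtype=float)
    keep = np.isfinite(y)
    if keep.sum() < 10:
        raise ValueError("need >= 10 lines with non-missing phenotype")
    X, y = X[keep], y[keep]
    Xc = X - X.mean(axis=0)
    sxx = np.sum(Xc**2, axis=0)
    return Xc, sxx, y, grid


def scanone_hk(
    cross: CrossPopulation,
    trait: str,
    step: float = 1.0,
    error_prob: float = 0.002,
    probs: GenotypeProbabilities | None = None,
) -> QtlScanResult:
    """Single-QTL genome scan by Haley–Knott regression.

    At every grid position the phenotype is regressed on the expected teosinte
    dosage; LOD = (n/2)·log10(RSS₀/RSS₁) against the intercept-only null.
    Lines with missing phenotype are dropped listwise.  Pass a precomputed
    ``probs`` to reuse genotype probabilities across traits/permutations.
    """
    Xc, sxx, y, grid = _prepare_scan(cross, trait, step, error_prob, probs)
    n = y.size
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    if rss0 <= 0:
        warnings.warn(f"trait {trait!r} is constant; all LOD = 0", stacklevel=2)
        lod = np.zeros(Xc.shape[1])
    else:
        lod = _lod_curve(Xc, sxx, yc, rss0, n)
    table = grid.copy()
    table["lod"] = lod
    return QtlScanResult(table=table, trait=trait)


def permutation_threshold(
    cross: CrossPopulation,
    trait: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    step: float = 1.0,
    error_prob: float = 0.002,
    probs: GenotypeProbabilities | None = None,
    return_maxima: bool = False,
):
    """Genome-wide LOD threshold from phenotype permutations.

    Permutes the phenotype vector against the (fixed) genotype matrix
    ``n_perm`` times, records each genome-wide maximum LOD, and returns the
    empirical (1 − alpha) quantile (type-7 / linear-interpolation rule).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Xc, sxx, y, _ = _prepare_scan(cross, trait, step, error_prob, probs)
    n = y.size
    maxima = np.empty(n_perm)
    chunk = 2000
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        Y = np.empty((n, m))
        for j in range(m):
            Y[:, j] = rng.permutation(y)
        Yc = Y - Y.mean(axis=0)
        rss0 = np.sum(Yc**2, axis=0)
        sxy = Xc.T @ Yc  # (P, m)
        with np.errstate(invalid="ignore", divide="ignore"):
            rss1 = rss0[None, :] - sxy**2 / sxx[:, None]
        rss1 = np.where(sxx[:, None] <= 0, rss0[None, :], rss1)
        rss1 = np.maximum(rss1, _LOD_RSS_FLOOR * rss0[None, :])
        lod = (n / 2.0) * np.log10(rss0[None, :] / rss1)
        maxima[start : start + m] = lod.max(axis=0)
    threshold = float(np.quantile(maxima, 1.0 - alpha, method="linear"))
    if return_maxima:
        return threshold, maxima
    return threshold


def bayes_interval(
    scan: QtlScanResult,
    chromosome: str,
    prob: float = 0.95,
) -> BayesInterval:
    """Bayes credible interval for QTL location on one chromosome.

    The posterior is proportional to 10^LOD over the chromosome's grid;
    positions are accumulated in decreasing posterior order until the
    cumulative mass reaches ``prob``, and the interval is expanded outward to
    the nearest flanking genotyped markers.
    """
    sub = scan.table[scan.table["chr"].astype(str) == str(chromosome)]
    if sub.empty:
        raise ValueError(f"scan does not cover chromosome {chromosome}")
    pos = sub["pos_cM"].to_numpy(dtype=float)
    lod = sub["lod"].to_numpy(dtype=float)
    is_marker = sub["is_marker"].to_numpy(dtype=bool)

    if np.ptp(lod) < 1e-12:
        warnings.warn(
            f"flat LOD on chromosome {chromosome}; whole-chromosome interval",
            stacklevel=2,
        )
        return BayesInterval(str(chromosome), float(pos.min()),
                             float(pos[np.argmax(lod)]), float(pos.max()), prob)

    w = np.power(10.0, lod - lod.max())
    w /= w.sum()
    order = np.argsort(w)[::-1]
    csum = np.cumsum(w[order])
    k = int(np.searchsorted(csum, prob)) + 1
    accepted = order[:k]
    lo, hi = float(pos[accepted].min()), float(pos[accepted].max())
    peak = float(pos[np.argmax(lod)])

    marker_pos = pos[is_marker]
    left = marker_pos[marker_pos <= lo]
    right = marker_pos[marker_pos >= hi]
    lo = float(left.max()) if left.size else float(pos.min())
    hi = float(right.min()) if right.size else float(pos.max())
    return BayesInterval(str(chromosome), lo, peak, hi, prob)
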