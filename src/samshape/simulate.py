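"""Synthetic inputs emulating the study system.

Three generators replace the study's micrographs and germplasm:

* :func:`simulate_cross` — a maize×teosinte BC2S3 population (F1, two
  backcrosses to the recurrent maize parent, three selfings) with meiosis
  simulated marker-interval by marker-interval from inverse-Kosambi
  recombination fractions (no interference — the same generative model the
  scanner's HMM assumes), additive QTL effects on SAM height and radius, and
  replicated noisy phenotype measurements with a per-replicate offset.
* :func:`simulate_contour` — a noisy near-parabolic open SAM outline
  y = h·(1 − (|x′|/r)^p) with a shear term for left/right lean and a
  peakedness exponent (p = 2 is a true parabola; p > 2 rounder, p < 2 more
  peaked), traced base → apex → base.
* :func:`simulate_taxa_panel` — a survey of diverse-taxa apex contours with
  parabolic coefficients drawn uniformly from a range, exercising the
  parabolic-fit survey.

Default population sizes (400 lines, 5 chromosomes × 50 markers × 100 cM,
2 replicates) are chosen so QTL recovery works at desk scale while keeping
simulation-heavy tests in the minutes range; phenotype baselines (height
100 μm, radius 55 μm) are realistic for 14-day maize seedling SAMs.
All randomness flows from the mandatory config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contours import Contour
from .qtl import CrossPopulation, GeneticMap, kosambi_to_recfrac

__all__ = [
    "QtlEffect",
    "SimulationConfig",
    "simulate_cross",
    "simulate_contour",
    "simulate_taxa_panel",
]


@dataclass(frozen=True)
class QtlEffect:
    """An additive QTL: chromosome, position (cM) and per-dosage trait effects.

    ``effect_height``/``effect_radius`` (μm) are the phenotype shifts of a
    homozygous-teosinte line relative to homozygous-maize; a heterozygote
    shifts by half (dosage coding 0, 1/2, 1).
    """

    chromosome: str
    position_cm: float
    effect_height: float = 0.0
    effect_radius: float = 0.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study population (units in field names)."""

    seed: int
    n_lines: int = 400
    n_chromosomes: int = 5
    markers_per_chromosome: int = 50
    chromosome_length_cm: float = 100.0
    qtl: list[QtlEffect] = field(default_factory=list)
    base_height_um: float = 100.0
    base_radius_um: float = 55.0
    residual_sd_height_um: float = 8.0
    residual_sd_radius_um: float = 5.0
    n_replicates: int = 2
    replicate_offset_sd_um: float = 2.0
    contour_points: int = 800
    contour_noise_sd_um: float = 1.0
    asymmetry_shear: float = 0.0
    peakedness_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.peakedness_exponent <= 0:
            raise ValueError("peakedness_exponent must be > 0")
        for q in self.qtl:
            if not (np.isfinite(q.effect_height) and np.isfinite(q.effect_radius)):
                raise ValueError("QTL effects must be finite")

    def rng_for(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage substream of the configured seed."""
        import zlib

        stage_key = zlib.crc32(stage.encode()) & 0x7FFFFFFF
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stage_key,))
        )


def _meiosis(h1: np.ndarray, h2: np.ndarray, rec: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per row from diplotype (h1, h2); crossovers Bernoulli(rec) per interval."""
    n, L = h1.shape
    start = rng.integers(0, 2, size=(n, 1))
    if L > 1:
        xo = rng.random((n, L - 1)) < rec[None, :]
        strand = (start + np.concatenate(
            [np.zeros((n, 1), dtype=int), np.cumsum(xo, axis=1)], axis=1)) % 2
    else:
        strand = start
    return np.where(strand == 0, h1, h2)


def simulate_cross(config: SimulationConfig) -> CrossPopulation:
    """Simulate a BC2S3 cross with additive QTL effects and replicated phenotypes.

    Gametes pass through F1 → two backcrosses to the maize parent → three
    selfings; each line is an independent pedigree.  Phenotypes are
    base + Σ effect·dosage + replicate offset + N(0, residual_sd), with
    dosage = (teosinte allele count)/2 at the QTL locus.  Returns a
    :class:`CrossPopulation` whose per-line phenotype table holds replicate
    means and whose ``replicated_phenotypes`` holds the raw long table;
    the true QTL dosages are attached as ``qtl_truth``.
    """
    rng = config.rng_for("cross")
    chroms = [str(c + 1) for c in range(config.n_chromosomes)]
    marker_pos = np.linspace(0.0, config.chromosome_length_cm, config.markers_per_chromosome)

    qtl_by_chrom: dict[str, list[QtlEffect]] = {c: [] for c in chroms}
    for q in config.qtl:
        ch = str(q.chromosome)
        if ch not in qtl_by_chrom:
            raise ValueError(f"QTL chromosome {ch!r} outside the map")
        if not 0.0 <= q.position_cm <= config.chromosome_length_cm:
            raise ValueError(f"QTL position {q.position_cm} cM outside the map")
        qtl_by_chrom[ch].append(q)

    n = config.n_lines
    geno_cols = []
    qtl_dosage: list[tuple[QtlEffect, np.ndarray]] = []
    marker_names: dict[str, list[str]] = {}
    positions: dict[str, np.ndarray] = {}

    for ch in chroms:
        qtls = sorted(qtl_by_chrom[ch], key=lambda q: q.position_cm)
        loci = np.union1d(np.round(marker_pos, 9), np.round([q.position_cm for q in qtls], 9))
        is_marker = np.isin(loci, np.round(marker_pos, 9))
        rec = kosambi_to_recfrac(np.diff(loci))

        # pedigree: maize haplotype = 0, teosinte = 1
        h1 = np.zeros((n, loci.size), dtype=np.int8)
        h2 = np.ones((n, loci.size), dtype=np.int8)
        for _ in range(2):  # backcrosses to maize
            g = _meiosis(h1, h2, rec, rng)
            h1, h2 = g, np.zeros_like(g)
        for _ in range(3):  # selfings
            g1 = _meiosis(h1, h2, rec, rng)
            g2 = _meiosis(h1, h2, rec, rng)
            h1, h2 = g1, g2

        geno = (h1 + h2).astype(np.int8)  # teosinte allele count per locus
        geno_cols.append(geno[:, is_marker])
        for q in qtls:
            j = int(np.searchsorted(loci, np.round(q.position_cm, 9)))
            qtl_dosage.append((q, geno[:, j] / 2.0))
        marker_names[ch] = [f"c{ch}m{j + 1}" for j in range(marker_pos.size)]
        positions[ch] = marker_pos.copy()

    genotypes = np.concatenate(geno_cols, axis=1)
    gmap = GeneticMap(chromosomes=chroms, marker_names=marker_names, positions=positions)

    line_ids = [f"MxT{i + 1:04d}" for i in range(n)]
    genetic_h = np.full(n, config.base_height_um)
    genetic_r = np.full(n, config.base_radius_um)
    for q, dose in qtl_dosage:
        genetic_h = genetic_h + q.effect_height * dose
        genetic_r = genetic_r + q.effect_radius * dose

    rep_offsets = rng.normal(0.0, config.replicate_offset_sd_um, size=config.n_replicates)
    rows = []
    for j in range(config.n_replicates):
        eh = rng.normal(0.0, config.residual_sd_height_um, size=n)
        er = rng.normal(0.0, config.residual_sd_radius_um, size=n)
        for i in range(n):
            rows.append(
                (line_ids[i], f"rep{j + 1}",
                 genetic_h[i] + rep_offsets[j] + eh[i],
                 genetic_r[i] + rep_offsets[j] + er[i])
            )
    replicated = pd.DataFrame(rows, columns=["line_id", "replicate", "height", "radius"])
    per_line = (
        replicated.groupby("line_id", sort=False)[["height", "radius"]].mean()
    ).loc[line_ids]

    cross = CrossPopulation(
        map=gmap,
        genotypes=genotypes,
        phenotypes=per_line,
        cross_design=(2, 3),
        replicated_phenotypes=replicated,
    )
    cross.qtl_truth = [  # type: ignore[attr-defined]
        {"chromosome": q.chromosome, "position_cm": q.position_cm,
         "effect_height": q.effect_height, "effect_radius": q.effect_radius,
         "dosage": dose}
        for q, dose in qtl_dosage
    ]
    cross.genetic_values = pd.DataFrame(  # type: ignore[attr-defined]
        {"height": genetic_h, "radius": genetic_r}, index=per_line.index
    )
    return cross


def simulate_contour(
    height: float,
    radius: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    contour_id: str = "",
) -> Contour:
    """A noisy open SAM contour: sheared power-parabola traced base → apex → base.

    The ideal outline is y = h·(1 − (|x′|/r)^p) for x′ ∈ [−r, r] with lean
    applied as x = x′ − shear·(y/h)·r; iid Gaussian displacement noise of SD
    ``contour_noise_sd_um`` is added to both coordinates.  Orientation is set
    to ``p0_left``.
    """
    if height <= 0 or radius <= 0:
        raise ValueError("height and radius must be > 0")
    if rng is None:
        rng = config.rng_for("contour")
    xp = np.linspace(-radius, radius, config.contour_points)
    y = height * (1.0 - (np.abs(xp) / radius) ** config.peakedness_exponent)
    x = xp - config.asymmetry_shear * (y / height) * radius
    pts = np.column_stack([x, y])
    if config.contour_noise_sd_um > 0:
        pts = pts + rng.normal(0.0, config.contour_noise_sd_um, size=pts.shape)
    return Contour(points=pts, contour_id=contour_id, orientation="p0_left")


def simulate_taxa_panel(
    n_taxa: int,
    coeff_range: tuple[float, float] = (0.005, 0.08),
    noise_sd: float = 2.0,
    seed: int = 0,
    height: float = 100.0,
    contour_points: int = 400,
) -> list[tuple[str, Contour]]:
    """Diverse-taxa apex survey: parabolic contours over a coefficient range.

    Parabolic coefficients (μm⁻¹) are drawn uniformly in ``coeff_range`` at
    fixed height; each taxon gets one noisy contour.  Returns
    (taxon_name, contour) pairs for the parabolic-fit survey path.
    """
    lo, hi = coeff_range
    if not (0 < lo < hi):
        raise ValueError("coeff_range must be a positive increasing interval")
    rng = np.random.default_rng(seed)
    coeffs = rng.uniform(lo, hi, n_taxa)  # drawn up front: reproducible from the seed
    out = []
    for t in range(n_taxa):
        radius = float(np.sqrt(height / coeffs[t]))
        cfg = SimulationConfig(seed=seed, contour_points=contour_points,
                               contour_noise_sd_um=noise_sd)
        contour = simulate_contour(height, radius, cfg, rng=rng, contour_id=f"taxon{t + 1:03d}")
        out.append((f"taxon{t + 1:03d}", contour))
    return out
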