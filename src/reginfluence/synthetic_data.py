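"""Synthetic genomes, binding sites and expression with the statistical
structure the influence model assumes.

The generator emulates two-tissue ChIP + microarray data: genes with TSSs
on one linear chromosome, tissue-specific binding sites scattered up to
+/-100 kb from TSSs, and log expression equal to a sum of
distance-dependent site contributions plus Gaussian noise.  Because the
true influence function and regulator weights are known, parameter
recovery on generated data is the package's main correctness surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .genome_model import (
    BindingSite,
    ExpressionTable,
    GeneBindingProfile,
    TSSAnnotation,
    associate_sites,
)

import pandas as pd

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "true_influence_presets",
    "generate_genome",
    "generate_sites",
    "generate_expression",
    "generate_dataset",
]

PRESET_NAMES = ("linear_decay_50kb", "asymmetric_upstream", "flat", "conservation_only")


def true_influence_presets(name: str) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Known ground-truth influence functions, f(d, conservation).

    * ``linear_decay_50kb`` — f(d) = max(0, 1 - |d| / 50000): influence
      falls off linearly and vanishes beyond 50 kb.
    * ``asymmetric_upstream`` — same decay with the upstream (d < 0) side
      multiplied by 1.2, mimicking a somewhat stronger effect of upstream
      sites.
    * ``flat`` — constant 1 within the association window.
    * ``conservation_only`` — influence equals the site's conservation
      score and ignores position entirely.
    """
    if name == "linear_decay_50kb":
        return lambda d, cons: np.maximum(0.0, 1.0 - np.abs(d) / 50_000.0)
    if name == "asymmetric_upstream":
        def f(d, cons):
            base = np.maximum(0.0, 1.0 - np.abs(d) / 50_000.0)
            return np.where(np.asarray(d) < 0, 1.2 * base, base)
        return f
    if name == "flat":
        return lambda d, cons: np.ones_like(np.asarray(d, dtype=float))
    if name == "conservation_only":
        return lambda d, cons: np.asarray(cons, dtype=float)
    raise ValueError(f"unknown influence preset {name!r}; choose from {PRESET_NAMES}")


@dataclass
class SyntheticSpec:
    """Study conditions for a two-tissue synthetic dataset.

    Distances are drawn from a mixture of a TSS-proximal Laplace component
    and a uniform component over the full +/-100 kb window, so most sites
    fall outside the proximal promoter while binding still concentrates
    near the TSS.  Conservation is drawn independently of influence (a
    bimodal Beta mixture), and ChIP enrichment is log-normal.
    """

    n_genes: int = 2000
    chrom: str = "chrS"
    chrom_length: int | None = None  # default: 25 kb of genome per gene
    min_gene_spacing: int = 2_000
    tissues: tuple[str, str] = ("tissueA", "tissueB")
    sites_per_gene_mean: float = 3.0
    tissue_unique_fraction: float = 0.5
    max_distance: int = 100_000
    proximal_fraction: float = 0.4
    proximal_scale: float = 5_000.0
    site_width: int = 200
    regulator_weights: dict[str, float] = field(
        default_factory=lambda: {"p300": 1.0, "CEBPA": 1.0, "FOXA1": 1.0, "E2F4": 1.0}
    )
    reference_regulator: str = "p300"
    influence_preset: str = "asymmetric_upstream"
    conservation_high_fraction: float = 0.5
    conservation_beta_low: tuple[float, float] = (2.0, 8.0)
    conservation_beta_high: tuple[float, float] = (8.0, 2.0)
    enrichment_meanlog: float = 2.0
    enrichment_sdlog: float = 0.7
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sites_per_gene_mean <= 0:
            raise ValueError("sites_per_gene_mean must be > 0")
        if not 0.0 <= self.tissue_unique_fraction <= 1.0:
            raise ValueError("tissue_unique_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.chrom_length is None:
            self.chrom_length = 25_000 * self.n_genes

    def true_influence(self):
        return true_influence_presets(self.influence_preset)


@dataclass
class SyntheticDataset:
    """A generated dataset plus the ground truth that produced it."""

    spec: SyntheticSpec
    genome: list[TSSAnnotation]
    sites: dict[str, list[BindingSite]]
    expression: ExpressionTable
    true_lambda: pd.DataFrame  # noiseless per-tissue contribution sums

    def truth_curve(self, grid) -> np.ndarray:
        f = self.spec.true_influence()
        return f(np.asarray(grid, dtype=float), 0.0)

    def truth_json(self) -> dict:
        grid = np.arange(-self.spec.max_distance, self.spec.max_distance + 1, 1000)
        spec = asdict(self.spec)
        spec["tissues"] = list(self.spec.tissues)
        return {
            "spec": spec,
            "curve_grid": grid.tolist(),
            "curve_values": self.truth_curve(grid).tolist(),
            "regulator_weights": self.spec.regulator_weights,
        }


def generate_genome(spec: SyntheticSpec, rng: np.random.Generator) -> list[TSSAnnotation]:
    """Place n_genes TSSs with a minimum spacing on one chromosome.

    Inter-gene gaps are min_spacing plus an exponential excess, so mean
    spacing is chrom_length / (n_genes + 1) and many genes lie within
    100 kb of several neighbours (multi-gene regulation arises naturally).
    """
    n = spec.n_genes
    slack = spec.chrom_length - (n + 1) * spec.min_gene_spacing
    if slack <= 0:
        raise ValueError(
            f"{n} genes with min spacing {spec.min_gene_spacing} bp do not fit "
            f"in {spec.chrom_length} bp"
        )
    raw = rng.exponential(scale=1.0, size=n + 1)
    gaps = spec.min_gene_spacing + raw / raw.sum() * slack
    positions = np.cumsum(gaps[:n]).astype(int) + 1
    strands = rng.choice(["+", "-"], size=n)
    width = len(str(n))
    return [
        TSSAnnotation(f"g{i:0{width}d}", spec.chrom, int(pos), str(strand))
        for i, (pos, strand) in enumerate(zip(positions, strands))
    ]


def _draw_distances(spec: SyntheticSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    proximal = rng.random(size) < spec.proximal_fraction
    d = np.where(
        proximal,
        rng.laplace(0.0, spec.proximal_scale, size),
        rng.uniform(-spec.max_distance, spec.max_distance, size),
    )
    return np.clip(d, -spec.max_distance, spec.max_distance)


def generate_sites(
    genome: list[TSSAnnotation], spec: SyntheticSpec, rng: np.random.Generator
) -> dict[str, list[BindingSite]]:
    """Scatter binding sites around each TSS, shared or tissue-unique.

    Each gene seeds a Poisson number of sites; a site is shared between
    both tissues with probability 1 - tissue_unique_fraction, otherwise it
    belongs to one tissue chosen at random.  Association back to genes is
    purely geometric, so a site seeded by one gene routinely falls within
    the cutoff of its neighbours too.
    """
    regulators = sorted(spec.regulator_weights)
    ta, tb = spec.tissues
    sites: dict[str, list[BindingSite]] = {ta: [], tb: []}
    counter = 0
    for g in genome:
        k = rng.poisson(spec.sites_per_gene_mean)
        if k == 0:
            continue
        d = _draw_distances(spec, k, rng)
        # d is signed in the transcription direction; map to genomic offset.
        genomic_offset = d if g.strand == "+" else -d
        mid = g.tss_pos + genomic_offset.astype(int)
        half = spec.site_width // 2
        start = np.maximum(0, mid - 1 - half)  # back to 0-based
        end = start + spec.site_width
        unique = rng.random(k) < spec.tissue_unique_fraction
        which = rng.choice([ta, tb], size=k)
        regs = rng.choice(regulators, size=k)
        high = rng.random(k) < spec.conservation_high_fraction
        a_lo, b_lo = spec.conservation_beta_low
        a_hi, b_hi = spec.conservation_beta_high
        cons = np.where(
            high, rng.beta(a_hi, b_hi, k), rng.beta(a_lo, b_lo, k)
        )
        enr = rng.lognormal(spec.enrichment_meanlog, spec.enrichment_sdlog, k)
        for j in range(k):
            counter += 1
            tissues_here = [which[j]] if unique[j] else [ta, tb]
            for t in tissues_here:
                sites[t].append(
                    BindingSite(
                        site_id=f"s{counter:06d}",
                        chrom=spec.chrom,
                        start=int(start[j]),
                        end=int(end[j]),
                        tissue=t,
                        regulators=frozenset([str(regs[j])]),
                        enrichment=float(enr[j]),
                        conservation=float(np.clip(cons[j], 0.0, 1.0)),
                    )
                )
    return sites


def _profile_lambda(
    profiles: list[GeneBindingProfile], spec: SyntheticSpec
) -> np.ndarray:
    """Noiseless contribution sum per gene under the true model."""
    f = spec.true_influence()
    out = np.zeros(len(profiles))
    for i, p in enumerate(profiles):
        if not p.entries:
            continue
        d = np.array([e.signed_distance for e in p.entries], dtype=float)
        cons = np.array(
            [e.conservation if e.conservation is not None else 0.0 for e in p.entries]
        )
        a = np.array(
            [
                np.mean([spec.regulator_weights.get(r, 1.0) for r in e.regulators])
                if e.regulators
                else 1.0
                for e in p.entries
            ]
        )
        out[i] = float(np.sum(a * e_alpha(p) * f(d, cons)))
    return out


def e_alpha(profile: GeneBindingProfile) -> np.ndarray:
    return np.array([e.alpha for e in profile.entries])


def generate_expression(
    genome: list[TSSAnnotation],
    sites: dict[str, list[BindingSite]],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[ExpressionTable, pd.DataFrame]:
    """Per-tissue log expression: true contribution sums plus Gaussian noise.

    Returns the expression table (with a ``differential`` flag set for
    genes whose noiseless contribution sums differ between tissues) and
    the noiseless sums themselves for recovery tests.
    """
    gene_ids = [g.gene_id for g in genome]
    lam = {}
    for t in spec.tissues:
        profiles = associate_sites(genome, sites[t], spec.max_distance)
        lam[t] = _profile_lambda(profiles, spec)
    true_lambda = pd.DataFrame(lam, index=gene_ids)
    noisy = {
        t: lam[t] + rng.normal(0.0, spec.noise_sd, len(gene_ids)) for t in spec.tissues
    }
    values = pd.DataFrame(noisy, index=gene_ids)
    ta, tb = spec.tissues
    differential = pd.Series(
        np.abs(true_lambda[ta] - true_lambda[tb]) > 1e-12, index=gene_ids
    )
    return ExpressionTable(values, differential), true_lambda


def generate_dataset(spec: SyntheticSpec, seed: int | None = None) -> SyntheticDataset:
    """Generate genome, sites and expression from one seed, with truth."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    genome = generate_genome(spec, rng)
    sites = generate_sites(genome, spec, rng)
    expression, true_lambda = generate_expression(genome, sites, spec, rng)
    return SyntheticDataset(spec, genome, sites, expression, true_lambda)
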