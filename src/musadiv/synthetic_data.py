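"""Mixed-ploidy SSR genotype simulator with known truth.

The generator mirrors the generative side of the admixture model the
pipeline infers: K ancestral populations with correlated allele
frequencies (population frequencies drawn from a Dirichlet centered on
the ancestral vector with concentration ``(1 - F_k) / F_k``), individual
membership vectors q from a symmetric Dirichlet, and, for an accession of
ploidy p, p allele copies per locus whose source populations are drawn
from q. Peak scoring is codominant but dosage-blind, so a genotype is the
SET of distinct observed sizes; null-allele copies drop out before
collapsing, and a whole locus can go missing. Flow-cytometry 2C readings
are drawn per ploidy class around 1.26 / 1.93 / 2.45 pg with a ~3.3%
coefficient of variation, and ITS band profiles follow each accession's
true A:B genome-set dosage.

A second generator builds genome-dosage groups (BB, ABB, AAB, AAA, ...)
from two disjoint ancestral allele pools, emulating the contrast in which
alleles common in the A-genome pool rise in frequency with A dosage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from musadiv.its_genotyper import call_genome, predict_band_profile
from musadiv.marker_stats import summarize_allele_counts  # noqa: F401  (re-export)
from musadiv.pipeline_io import AccessionRecord, GenotypeTable

#: genome-set compositions (a_sets, b_sets) per ploidy, with draw weights
#: shaped like the collection's make-up (AA-rich diploids, AAB-rich
#: triploids, mostly AAAB tetraploids).
_COMPOSITIONS = {
    2: ([(2, 0), (1, 1), (0, 2)], [0.8, 0.08, 0.12]),
    3: ([(3, 0), (2, 1), (1, 2)], [0.37, 0.45, 0.18]),
    4: ([(4, 0), (3, 1)], [0.2, 0.8]),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults follow the collection being emulated: 16 SSR loci with 7-15
    alleles each, ploidies 2/3/4 in collection-like proportions, 2C class
    means 1.26/1.93/2.45 pg with CV 3.31%, and K = 3 source populations at
    divergence F = 0.05 for 60 accessions (the scale used throughout the
    recovery studies). ``alpha_q = 0.1`` keeps most accessions near-pure
    with a minority of admixed hybrids, as in a germplasm collection.
    """

    K: int = 3
    n_accessions: int = 60
    ploidy_proportions: tuple[float, float, float] = (0.35, 0.50, 0.15)  # 2x, 3x, 4x
    L: int = 16
    alleles_per_locus: tuple[int, int] = (7, 15)
    f_range: tuple[float, float] = (0.05, 0.05)
    alpha_q: float = 0.1
    missing_rate: float = 0.02
    null_allele_rate: float = 0.02
    two_c_means: tuple[float, float, float] = (1.26, 1.93, 2.45)
    two_c_cv: float = 3.31  # percent
    allele_size_range: tuple[int, int] = (80, 350)
    seed: int = 20130312

    def __post_init__(self) -> None:
        for rate in (self.missing_rate, self.null_allele_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.L < 1 or self.alleles_per_locus[0] < 2:
            raise ValueError("need L >= 1 and >= 2 alleles per locus")
        if abs(sum(self.ploidy_proportions) - 1.0) > 1e-9:
            raise ValueError("ploidy proportions must sum to 1")


@dataclass
class SimTruth:
    """Ground truth behind a simulated table."""

    K: int
    F: np.ndarray  # (K,)
    allele_sizes: list[np.ndarray]  # per locus, observed size per index
    ancestral_freqs: list[np.ndarray]  # per locus
    pop_freqs: list[np.ndarray]  # per locus, (K, J_l)
    ploidy: np.ndarray  # (n,)
    genome: list[tuple[int, int]]  # (a_sets, b_sets) per accession
    q: np.ndarray  # (n, K)
    two_c: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        for pa, pp in zip(self.ancestral_freqs, self.pop_freqs):
            if abs(pa.sum() - 1.0) > 1e-9 or not np.allclose(pp.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("frequency vectors must sum to 1")


def _draw_f(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.f_range
    return rng.uniform(lo, hi, size=cfg.K) if hi > lo else np.full(cfg.K, lo)


def generate_population(cfg: SimConfig) -> tuple[GenotypeTable, list[AccessionRecord], SimTruth]:
    """Simulate a genotype table, accession records, and the truth behind them.

    The same config (seed included) always returns identical outputs.
    An accession of ploidy p contributes p allele copies per locus; each
    copy's source population is drawn from its q and the copy's allele from
    that population's frequency vector; the stored genotype collapses to
    the set of distinct surviving sizes.
    """
    rng = np.random.default_rng(cfg.seed)
    f_vec = _draw_f(cfg, rng)
    sizes, ancestral, pop_freqs = [], [], []
    lo, hi = cfg.alleles_per_locus
    for _ in range(cfg.L):
        j = int(rng.integers(lo, hi + 1))
        sizes.append(np.sort(rng.choice(
            np.arange(cfg.allele_size_range[0], cfg.allele_size_range[1] + 1),
            j, replace=False)))
        pa = rng.dirichlet(np.ones(j))
        ancestral.append(pa)
        pop_freqs.append(np.vstack([
            rng.dirichlet(np.maximum(pa * (1.0 - f) / f, 1e-9)) for f in f_vec
        ]))

    n = cfg.n_accessions
    ploidy = rng.choice([2, 3, 4], size=n, p=cfg.ploidy_proportions)
    q = rng.dirichlet(np.full(cfg.K, cfg.alpha_q), size=n)
    genome = []
    for p in ploidy:
        comps, weights = _COMPOSITIONS[int(p)]
        genome.append(comps[rng.choice(len(comps), p=weights)])
    means = dict(zip((2, 3, 4), cfg.two_c_means))
    two_c = np.array([
        rng.normal(means[int(p)], cfg.two_c_cv / 100.0 * means[int(p)]) for p in ploidy
    ])

    calls: list[list[tuple[int, ...] | None]] = [[None] * cfg.L for _ in range(n)]
    for l in range(cfg.L):
        pf = pop_freqs[l]
        sz = sizes[l]
        for i in range(n):
            if rng.random() < cfg.missing_rate:
                continue
            observed = []
            for _ in range(int(ploidy[i])):
                z = rng.choice(cfg.K, p=q[i])
                a = rng.choice(len(sz), p=pf[z])
                if rng.random() >= cfg.null_allele_rate:
                    observed.append(int(sz[a]))
            if observed:
                calls[i][l] = tuple(sorted(set(observed)))

    accession_ids = [f"SIM-{i + 1:03d}" for i in range(n)]
    locus_names = [f"L{l + 1:02d}" for l in range(cfg.L)]
    table = GenotypeTable(accession_ids, locus_names, calls)

    records = []
    for i in range(n):
        a_sets, b_sets = genome[i]
        profile = predict_band_profile(a_sets, b_sets)
        its_call = "/".join(sorted(call_genome(profile, int(ploidy[i])).candidates))
        records.append(AccessionRecord(
            index=i + 1,
            name=accession_ids[i],
            passport_genome="A" * a_sets + "B" * b_sets,
            section_musa=True,
            two_c=float(two_c[i]),
            printed_ploidy=int(ploidy[i]),
            its_530=profile.i530,
            its_350=profile.i350,
            its_180=profile.i180,
            its_genome_call=its_call,
            ssr_genome_call="",
        ))

    truth = SimTruth(
        K=cfg.K, F=f_vec, allele_sizes=sizes, ancestral_freqs=ancestral,
        pop_freqs=pop_freqs, ploidy=ploidy.astype(int), genome=genome, q=q, two_c=two_c,
    )
    return table, records, truth


def generate_dosage_population(
    groups: dict[str, tuple[int, int, int]],
    L: int = 16,
    alleles_per_pool: int = 6,
    seed: int = 20130312,
    concentration: float = 0.5,
    allele_size_range: tuple[int, int] = (80, 350),
) -> tuple[GenotypeTable, dict[str, str]]:
    """Simulate genome-dosage groups from disjoint A and B allele pools.

    ``groups`` maps a label to ``(a_sets, b_sets, count)``; at every locus
    an accession draws its a_sets copies from the A-pool frequency vector
    and its b_sets copies from the (allelically disjoint) B pool, then
    collapses to distinct sizes. Returns the table and accession -> label
    mapping. Under this construction an allele common in the A pool has
    carrier frequency non-decreasing in A dosage.
    """
    rng = np.random.default_rng(seed)
    lo, hi = allele_size_range
    pool_a, pool_b, freq_a, freq_b = [], [], [], []
    for _ in range(L):
        sz = rng.choice(np.arange(lo, hi + 1), 2 * alleles_per_pool, replace=False)
        pool_a.append(np.sort(sz[:alleles_per_pool]))
        pool_b.append(np.sort(sz[alleles_per_pool:]))
        freq_a.append(rng.dirichlet(np.full(alleles_per_pool, concentration)))
        freq_b.append(rng.dirichlet(np.full(alleles_per_pool, concentration)))

    accessions, labels, calls = [], {}, []
    for label, (a_sets, b_sets, count) in groups.items():
        for c in range(count):
            acc = f"{label}-{c + 1:03d}"
            accessions.append(acc)
            labels[acc] = label
            row: list[tuple[int, ...] | None] = []
            for l in range(L):
                copies = [int(pool_a[l][rng.choice(len(pool_a[l]), p=freq_a[l])])
                          for _ in range(a_sets)]
                copies += [int(pool_b[l][rng.choice(len(pool_b[l]), p=freq_b[l])])
                           for _ in range(b_sets)]
                row.append(tuple(sorted(set(copies))))
            calls.append(row)
    table = GenotypeTable(accessions, [f"L{l + 1:02d}" for l in range(L)], calls)
    return table, labels
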