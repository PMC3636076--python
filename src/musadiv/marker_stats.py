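"""SSR diversity statistics.

Two views of a microsatellite dataset are used side by side:

* a dominant (binary band) view, where each observed (locus, allele size)
  pair is scored present/absent per accession. Informativeness is the
  binary polymorphic information content ``PIC_i = 2 f_i (1 - f_i)``
  (maximum 0.5 at band frequency 1/2), combined with the effective
  multiplex ratio ``EMR = Na * beta`` (band count times polymorphic
  fraction) into the Marker Index ``MI = PIC * EMR``;
* a codominant view for diploids, with the Botstein polymorphic
  information content ``1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2`` and
  observed heterozygosity (fraction of two-allele genotypes).

A dosage-frequency trend utility tracks the carrier frequency of a
reference group's most frequent alleles across other genomic groups, the
pattern used to argue that triploid/tetraploid cultivars inherited the
common cultivated-diploid alleles in proportion to genome dosage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from musadiv.distance_clustering import BinaryMatrix
from musadiv.pipeline_io import GenotypeTable


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    n_alleles: int
    beta: float
    pic_binary_mean: float
    emr: float
    mi: float


def pic_binary(f: float) -> float:
    """Binary-band polymorphic information content, ``2 f (1 - f)``."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("band frequency must lie in [0, 1]")
    return 2.0 * f * (1.0 - f)


def marker_index(pic: float, n_bands: int, n_polymorphic: int) -> tuple[float, float]:
    """(EMR, MI) from a locus PIC and its band counts.

    EMR = Na * (polymorphic / Na) = number of polymorphic bands;
    MI = PIC * EMR.
    """
    if n_bands == 0:
        raise ValueError("locus has no bands")
    if not 0 <= n_polymorphic <= n_bands:
        raise ValueError("0 <= n_polymorphic <= n_bands required")
    emr = n_bands * (n_polymorphic / n_bands)
    return emr, pic * emr


def pic_codominant(freqs) -> float:
    """Botstein codominant PIC: ``1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``."""
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("negative allele frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("allele frequencies must sum to 1")
    sq = p**2
    # sum_{i<j} p_i^2 p_j^2 = ((sum sq)^2 - sum sq^2) / 2
    cross = (sq.sum() ** 2 - (sq**2).sum()) / 2.0
    return float(1.0 - sq.sum() - 2.0 * cross)


def observed_heterozygosity(genotypes: list[tuple[int, ...] | None]) -> float:
    """Fraction of non-missing diploid genotypes with two distinct alleles."""
    n = het = 0
    for g in genotypes:
        if g is None:
            continue
        k = len(set(g))
        if k > 2:
            raise ValueError(f"diploid genotype {g} has >2 distinct alleles")
        n += 1
        het += k == 2
    return het / n if n else float("nan")


def locus_summaries(binary: BinaryMatrix) -> pd.DataFrame:
    """Per-locus Na, beta, mean binary PIC, EMR and MI from band data.

    A band is polymorphic when it is present in at least one and absent in
    at least one accession with determined data at that locus; band
    frequencies are computed over non-missing rows only.
    """
    rows = []
    for locus in binary.locus_names:
        cols = [j for j, (l, _) in enumerate(binary.columns) if l == locus]
        sub = binary.values[:, cols]
        pics, poly = [], 0
        for j in range(sub.shape[1]):
            col = sub[:, j]
            obs = col[~np.isnan(col)]
            f = float(obs.mean()) if len(obs) else 0.0
            pics.append(pic_binary(f))
            poly += 0.0 < f < 1.0
        emr, mi = marker_index(float(np.mean(pics)), len(cols), poly)
        rows.append(
            LocusSummary(
                locus=locus,
                n_alleles=len(cols),
                beta=poly / len(cols),
                pic_binary_mean=float(np.mean(pics)),
                emr=emr,
                mi=mi,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("locus")


def group_diploid_stats(
    table: GenotypeTable, groups: dict[str, str], which: set[str] | None = None
) -> pd.DataFrame:
    """Per-group mean observed heterozygosity and codominant PIC (diploids).

    ``groups`` maps accession id -> group label; only listed accessions are
    used. Allele frequencies per locus are carrier-based over the group's
    non-missing genotypes.
    """
    out = []
    labels = sorted(set(groups.values()) if which is None else which)
    for label in labels:
        accs = [a for a, g in groups.items() if g == label]
        idx = [table.accessions.index(a) for a in accs]
        ho_per_locus, pic_per_locus = [], []
        for j in range(table.n_loci):
            genos = [table.calls[i][j] for i in idx]
            present = [g for g in genos if g is not None]
            if not present:
                continue
            ho_per_locus.append(observed_heterozygosity(genos))
            counts: dict[int, int] = {}
            for g in present:
                for a in set(g):
                    counts[a] = counts.get(a, 0) + 1
            freqs = np.array(list(counts.values()), dtype=float)
            pic_per_locus.append(pic_codominant(freqs / freqs.sum()))
        out.append(
            {
                "group": label,
                "n": len(accs),
                "ho_mean": float(np.mean(ho_per_locus)),
                "pic_codominant_mean": float(np.mean(pic_per_locus)),
            }
        )
    return pd.DataFrame(out).set_index("group")


def dosage_frequency_trend(
    table: GenotypeTable,
    groups: dict[str, str],
    reference_group: str,
    top_n: int = 20,
) -> pd.DataFrame:
    """Carrier frequency of the reference group's top alleles in every group.

    Frequency = fraction of a group's accessions carrying the allele,
    counted over accessions with determined data at the allele's locus.
    Ties at rank ``top_n`` break by allele size ascending (then locus name).
    """
    members: dict[str, list[int]] = {}
    for acc, grp in groups.items():
        members.setdefault(grp, []).append(table.accessions.index(acc))
    if not members.get(reference_group):
        raise ValueError(f"reference group {reference_group!r} is empty")

    def carrier_freq(idx: list[int], locus_j: int, allele: int) -> float:
        genos = [table.calls[i][locus_j] for i in idx]
        present = [g for g in genos if g is not None]
        if not present:
            return 0.0
        return sum(allele in g for g in present) / len(present)

    ref_idx = members[reference_group]
    candidates = []
    for j, locus in enumerate(table.locus_names):
        alleles = set()
        for i in ref_idx:
            if table.calls[i][j] is not None:
                alleles.update(table.calls[i][j])
        for a in alleles:
            candidates.append((carrier_freq(ref_idx, j, a), j, locus, a))
    candidates.sort(key=lambda t: (-t[0], t[3], t[2]))
    top = candidates[:top_n]

    rows = []
    for freq, j, locus, allele in top:
        row = {"locus": locus, "allele": allele, reference_group: freq}
        for grp, idx in members.items():
            if grp != reference_group:
                row[grp] = carrier_freq(idx, j, allele)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_allele_counts(
    table: GenotypeTable, class_labels: dict[str, str]
) -> pd.DataFrame:
    """% of non-missing (accession, locus) cells with 1-4 distinct alleles.

    ``class_labels`` maps accession id -> class (e.g. genomic group or
    ploidy class); percentages within each class sum to 100.
    """
    counts: dict[str, np.ndarray] = {}
    for acc, label in class_labels.items():
        i = table.accessions.index(acc)
        tally = counts.setdefault(label, np.zeros(4))
        for cell in table.calls[i]:
            if cell is None:
                continue
            k = len(set(cell))
            tally[min(k, 4) - 1] += 1
    data = {
        label: 100.0 * tally / tally.sum() if tally.sum() else tally
        for label, tally in counts.items()
    }
    return pd.DataFrame(data, index=[1, 2, 3, 4]).sort_index(axis=1)
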