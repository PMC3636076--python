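"""Triploid standardization of mixed-ploidy SSR genotypes.

Admixture inference needs a fixed number of allele slots per individual,
but the collection mixes diploids, triploids and tetraploids whose SSR
peaks give only the set of distinct alleles (dosage unobserved). All
accessions are therefore standardized to three slots per locus:

* 3 distinct alleles -> the three alleles;
* 2 distinct alleles -> one allele duplicated — the smaller one in
  Analysis I, the larger in Analysis II (an A1A2 profile becomes A1A1A2
  or A1A2A2), producing two alternative matrices whose downstream
  membership matrices are compared by per-group Pearson correlation;
* 1 distinct allele -> triplicated;
* more distinct alleles than slots allow (diploid with 3+, triploid or
  tetraploid with 4) -> the locus is set missing for that accession.

For tetraploids with four observed alleles there is no principled choice
of which three to keep; the default drops the locus, with an optional
policy that drops the largest allele instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from musadiv.pipeline_io import GenotypeTable

log = logging.getLogger("musadiv")

MISSING_SLOT = -9

ANALYSIS_I = "I"
ANALYSIS_II = "II"


@dataclass
class EncodedMatrix:
    """Accessions x loci x 3 allele slots; ``-9`` marks missing slots."""

    accessions: list[str]
    locus_names: list[str]
    slots: np.ndarray  # int64, shape (n, L, 3)
    variant: str

    def __post_init__(self) -> None:
        if self.variant not in (ANALYSIS_I, ANALYSIS_II):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.slots.shape != (len(self.accessions), len(self.locus_names), 3):
            raise ValueError("slot array shape mismatch")
        miss = self.slots == MISSING_SLOT
        if not (miss.all(axis=2) | (~miss).all(axis=2)).all():
            raise ValueError("a locus's 3 slots must be all missing or all set")


def standardize_to_triploid(
    alleles: tuple[int, ...],
    ploidy: int,
    variant: str = ANALYSIS_I,
    four_allele_policy: str = "missing",
) -> tuple[int, int, int] | None:
    """Reduce one genotype to 3 slots, or ``None`` when it must go missing."""
    if not alleles:
        raise ValueError("empty allele multiset")
    if ploidy not in (2, 3, 4):
        raise ValueError("ploidy must be 2, 3 or 4")
    if variant not in (ANALYSIS_I, ANALYSIS_II):
        raise ValueError(f"unknown variant {variant!r}")
    distinct = sorted(set(alleles))
    if ploidy == 2 and len(distinct) > 2:
        return None
    if len(distinct) == 4:
        if ploidy == 4 and four_allele_policy == "drop_largest":
            distinct = distinct[:3]
        else:
            return None
    if len(distinct) == 1:
        return (distinct[0],) * 3
    if len(distinct) == 2:
        lo, hi = distinct
        return (lo, lo, hi) if variant == ANALYSIS_I else (lo, hi, hi)
    return tuple(distinct)  # 3 distinct alleles


def build_matrices(
    table: GenotypeTable,
    ploidies: dict[str, int | str],
    four_allele_policy: str = "missing",
) -> tuple[EncodedMatrix, EncodedMatrix]:
    """Encode a genotype table into the two analysis variants.

    ``ploidies`` maps accession id to 2/3/4; accessions with mixoploid or
    indeterminate ploidy (any non-integer value, or absent id) are excluded
    with a logged warning, since the encoding needs a ploidy per accession.
    Both matrices cover identical accessions and loci and differ exactly at
    cells with two distinct alleles.
    """
    kept, skipped = [], []
    for acc in table.accessions:
        p = ploidies.get(acc)
        if p in (2, 3, 4):
            kept.append(acc)
        else:
            skipped.append(acc)
    if skipped:
        log.warning("excluded %d accession(s) without determinate ploidy: %s",
                    len(skipped), ", ".join(map(str, skipped)))
    n, L = len(kept), table.n_loci
    out = {}
    for variant in (ANALYSIS_I, ANALYSIS_II):
        slots = np.full((n, L, 3), MISSING_SLOT, dtype=np.int64)
        for i, acc in enumerate(kept):
            row = table.calls[table.accessions.index(acc)]
            for j in range(L):
                if row[j] is None:
                    continue
                enc = standardize_to_triploid(row[j], int(ploidies[acc]), variant,
                                              four_allele_policy)
                if enc is not None:
                    slots[i, j, :] = enc
        out[variant] = EncodedMatrix(kept, list(table.locus_names), slots, variant)
    log.info("encoded %d accessions x %d loci into Analysis I/II matrices", n, L)
    return out[ANALYSIS_I], out[ANALYSIS_II]


def compare_memberships(
    q_one: np.ndarray, q_two: np.ndarray, groups: list | np.ndarray
) -> dict[object, float | None]:
    """Per-group Pearson r between two aligned membership matrices.

    Columns of ``q_two`` are first aligned to ``q_one`` (label switching is
    unidentifiable across independent runs); the correlation is then taken
    over the vectorized rows of each group's members. Constant vectors give
    an undefined correlation, reported as ``None``.
    """
    from musadiv.admixture_inference import align_labels

    q_one = np.asarray(q_one, dtype=float)
    q_two = np.asarray(q_two, dtype=float)
    if q_one.shape != q_two.shape:
        raise ValueError("membership matrices must have equal shapes")
    if not np.allclose(q_one.sum(axis=1), 1.0, atol=1e-6) or not np.allclose(
        q_two.sum(axis=1), 1.0, atol=1e-6
    ):
        raise ValueError("membership rows must sum to 1")
    q_two = align_labels([q_one, q_two], reference=0)[1]
    groups = np.asarray(groups)
    result: dict[object, float | None] = {}
    for g in sorted(set(groups.tolist())):
        rows = groups == g
        x, y = q_one[rows].ravel(), q_two[rows].ravel()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            result[g] = None
        else:
            result[g] = float(np.corrcoef(x, y)[0, 1])
    return result
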