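"""Readers, writers and domain containers for the characterization pipeline.

On-disk formats
---------------
genotype CSV
    Comma-delimited; first column ``accession``, remaining columns one per
    SSR locus. A cell holds slash-separated allele sizes in base pairs
    (``"101/105"``) or the missing code ``"-9"``. Allele multiplicity is
    preserved.
triploid-coded (Structure-style) matrix
    Whitespace-delimited; a header of locus names, then three consecutive
    rows per accession (one allele slot each), missing slots ``-9``.
Newick
    Branch lengths written to 6 decimals; labels containing spaces or
    Newick metacharacters are single-quoted.

The packaged accession table transcribes the 224-row characterization table
of the Embrapa ex situ *Musa* collection (passport genome, flow-cytometry
2C value, ploidy, and ITS PCR-RFLP band intensities at the 530/350/180 bp
diagnostic fragments).
"""

from __future__ import annotations

import csv
import enum
import logging
import unicodedata
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

log = logging.getLogger("musadiv")

MISSING_CODE = "-9"

#: Sentinels for non-numeric 2C entries ("M" and "?" in the printed table).
MIXOPLOID = "MIXOPLOID"
UNDETERMINED = "UNDETERMINED"


class Intensity(enum.IntEnum):
    """Qualitative gel band intensity (blank, "+", "++")."""

    ABSENT = 0
    WEAK = 1
    STRONG = 2


_INTENSITY_FROM_CODE = {"": Intensity.ABSENT, "+": Intensity.WEAK, "++": Intensity.STRONG}


@dataclass(frozen=True)
class AccessionRecord:
    """One row of the collection characterization table.

    ``two_c`` is the flow-cytometry 2C DNA content in pg, or one of the
    sentinels :data:`MIXOPLOID` / :data:`UNDETERMINED`. ``printed_ploidy``
    is the ploidy as printed (2, 3, 4) or ``None`` when unknown.
    """

    index: int
    name: str
    passport_genome: str | None
    section_musa: bool
    two_c: float | str
    printed_ploidy: int | None
    its_530: Intensity
    its_350: Intensity
    its_180: Intensity
    its_genome_call: str
    ssr_genome_call: str

    def __post_init__(self) -> None:
        if isinstance(self.two_c, float) and not (0.0 < self.two_c < 10.0):
            raise ValueError(f"2C value {self.two_c} pg outside plausible (0, 10) range")


@dataclass
class GenotypeTable:
    """Accessions x SSR loci, each cell an allele multiset or missing.

    ``calls[i][j]`` is a sorted tuple of integer allele sizes (bp) for
    accession ``i`` at locus ``j``, or ``None`` when the locus failed to
    amplify. Multiplicity within a cell is preserved as read.
    """

    accessions: list[str]
    locus_names: list[str]
    calls: list[list[tuple[int, ...] | None]]

    def __post_init__(self) -> None:
        if len(set(self.accessions)) != len(self.accessions):
            dup = sorted({a for a in self.accessions if self.accessions.count(a) > 1})
            raise ValueError(f"duplicate accession id(s): {', '.join(dup)}")
        for row in self.calls:
            for cell in row:
                if cell is None:
                    continue
                if not 1 <= len(cell) <= 4:
                    raise ValueError(f"cell {cell} holds {len(cell)} alleles (1-4 allowed)")
                if any(a <= 0 for a in cell):
                    raise ValueError(f"non-positive allele size in {cell}")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def cell(self, accession: str, locus: str) -> tuple[int, ...] | None:
        return self.calls[self.accessions.index(accession)][self.locus_names.index(locus)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.accessions == other.accessions
            and self.locus_names == other.locus_names
            and self.calls == other.calls
        )


@dataclass
class PipelineConfig:
    """Tunable parameters shared by the pipeline stages.

    Chain-length defaults follow the original study protocol (burn-in
    150,000 then 70,000 recorded sweeps, K from 2 to 30, ten runs per K);
    tests and the bundled validation study use far shorter chains.
    """

    seed: int = 20130312
    k_min: int = 2
    k_max: int = 30
    runs_per_k: int = 10
    burnin: int = 150_000
    iters: int = 70_000
    #: 2C windows (pg) per ploidy class; printed per-class ranges padded
    #: by >= 0.08 pg and kept disjoint.
    ploidy_windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"2x": (1.10, 1.55), "3x": (1.75, 2.15), "4x": (2.20, 2.70)}
    )
    #: minimum nuclei fraction for a secondary peak to count toward mixoploidy
    min_peak_fraction: float = 0.2
    #: B-genome dose fraction at which the 350/180 bp bands read STRONG
    b_strong_threshold: float = 2.0 / 3.0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("require 1 <= k_min <= k_max")
        if self.burnin < 1 or self.iters < 1:
            raise ValueError("burnin and iters must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        windows = raw.pop("ploidy_windows", None)
        cfg = cls(**raw)
        if windows is not None:
            cfg = replace(cfg, ploidy_windows={k: tuple(v) for k, v in windows.items()})
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "k_min": self.k_min,
            "k_max": self.k_max,
            "runs_per_k": self.runs_per_k,
            "burnin": self.burnin,
            "iters": self.iters,
            "ploidy_windows": {k: list(v) for k, v in self.ploidy_windows.items()},
            "min_peak_fraction": self.min_peak_fraction,
            "b_strong_threshold": self.b_strong_threshold,
            "out_dir": self.out_dir,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# genotype CSV


def _parse_cell(cell: str, row: int, column: str) -> tuple[int, ...] | None:
    cell = cell.strip()
    if cell == MISSING_CODE:
        return None
    try:
        alleles = tuple(sorted(int(tok) for tok in cell.split("/")))
    except ValueError:
        raise ValueError(f"unparseable genotype cell {cell!r} at row {row}, column {column!r}")
    if len(alleles) > 4:
        raise ValueError(f">4 alleles in cell {cell!r} at row {row}, column {column!r}")
    if any(a <= 0 for a in alleles):
        raise ValueError(f"non-positive allele size at row {row}, column {column!r}")
    return alleles


def read_genotype_table(path: str | Path) -> GenotypeTable:
    """Read a genotype CSV (see module docstring for the dialect)."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        loci = [h.strip() for h in header[1:]]
        accessions: list[str] = []
        calls: list[list[tuple[int, ...] | None]] = []
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue
            acc = row[0].strip()
            if acc in accessions:
                raise ValueError(f"duplicate accession id: {acc}")
            if len(row) - 1 != len(loci):
                raise ValueError(f"row {rownum} has {len(row) - 1} cells, expected {len(loci)}")
            accessions.append(acc)
            calls.append([_parse_cell(c, rownum, loci[j]) for j, c in enumerate(row[1:])])
    table = GenotypeTable(accessions, loci, calls)
    log.info("read genotype table: %d accessions x %d loci from %s",
             table.n_accessions, table.n_loci, path)
    return table


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accession", *table.locus_names])
        for acc, row in zip(table.accessions, table.calls):
            writer.writerow(
                [acc] + [MISSING_CODE if c is None else "/".join(map(str, c)) for c in row]
            )


# ---------------------------------------------------------------------------
# packaged collection table

_NON_MUSA_SECTION_ROWS = {1, 222, 224}  # ornamental (Rhodochlamys-related) entries


def _record_from_csv_row(row: dict[str, str]) -> AccessionRecord:
    idx = int(row["index"])
    raw_2c = row["two_c"]
    if raw_2c == "M":
        two_c: float | str = MIXOPLOID
    elif raw_2c == "?":
        two_c = UNDETERMINED
    else:
        two_c = float(raw_2c)
    ploidy = {"2x": 2, "3x": 3, "4x": 4}.get(row["printed_ploidy"])
    genome = row["passport_genome"].strip() or None
    return AccessionRecord(
        index=idx,
        name=unicodedata.normalize("NFC", row["name"]),
        passport_genome=genome,
        section_musa=idx not in _NON_MUSA_SECTION_ROWS,
        two_c=two_c,
        printed_ploidy=ploidy,
        its_530=_INTENSITY_FROM_CODE[row["its_530"].strip()],
        its_350=_INTENSITY_FROM_CODE[row["its_350"].strip()],
        its_180=_INTENSITY_FROM_CODE[row["its_180"].strip()],
        its_genome_call=row["its_genome"].strip(),
        ssr_genome_call=row["ssr_genome"].strip(),
    )


def load_table1_fixture() -> list[AccessionRecord]:
    """Load the packaged 224-accession characterization table.

    Intensity codes map ``++`` -> STRONG, ``+`` -> WEAK, blank -> ABSENT;
    2C entries ``M`` -> :data:`MIXOPLOID` and ``?`` -> :data:`UNDETERMINED`.
    Rows are matched by index (names repeat in the collection).
    """
    text = resources.files("musadiv.data").joinpath("table1.csv").read_text(encoding="utf-8")
    records = [_record_from_csv_row(row) for row in csv.DictReader(text.splitlines())]
    if len(records) != 224:
        raise ValueError(f"collection table has {len(records)} rows, expected 224")
    return records


# ---------------------------------------------------------------------------
# triploid-coded (Structure-style) matrix


def write_structure_matrix(matrix, path: str | Path) -> None:
    """Write an :class:`~musadiv.structure_encoding.EncodedMatrix`.

    Three consecutive lines per accession (one allele slot each), one
    column per locus, missing slots as ``-9``; ordering is accession index
    then slot, so output is deterministic byte-for-byte. The format is
    whitespace-delimited, so spaces in accession ids become underscores.
    """
    with open(path, "w") as fh:
        fh.write("accession " + " ".join(matrix.locus_names) + "\n")
        for i, acc in enumerate(matrix.accessions):
            label = str(acc).replace(" ", "_")
            for slot in range(3):
                values = [int(matrix.slots[i, j, slot]) for j in range(len(matrix.locus_names))]
                fh.write(label + " " + " ".join(map(str, values)) + "\n")


def read_structure_matrix(path: str | Path, variant: str = "I"):
    """Inverse of :func:`write_structure_matrix` (round-trip lossless)."""
    from musadiv.structure_encoding import EncodedMatrix

    lines = Path(path).read_text().splitlines()
    loci = lines[0].split()[1:]
    body = [ln.split() for ln in lines[1:] if ln.strip()]
    if len(body) % 3:
        raise ValueError("triploid-coded matrix must have 3 rows per accession")
    accessions = [body[i][0] for i in range(0, len(body), 3)]
    n = len(accessions)
    slots = np.full((n, len(loci), 3), -9, dtype=np.int64)
    for i in range(n):
        for slot in range(3):
            row = body[3 * i + slot]
            if row[0] != accessions[i]:
                raise ValueError(f"rows for accession {accessions[i]} are not consecutive")
            slots[i, :, slot] = [int(v) for v in row[1:]]
    return EncodedMatrix(accessions=accessions, locus_names=loci, slots=slots, variant=variant)


# ---------------------------------------------------------------------------
# Newick

_NEEDS_QUOTING = set(" ()[]{}:;,'\"\t\n")


def _newick_label(name: str) -> str:
    if any(ch in _NEEDS_QUOTING for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree) -> str:
    """Serialize an (unrooted, trifurcating-root) ``skbio.TreeNode``.

    Branch lengths are written to 6 decimals; labels containing spaces or
    metacharacters are single-quoted.
    """

    def render(node) -> str:
        if node.is_tip():
            label = _newick_label(node.name or "")
        else:
            label = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                label += _newick_label(node.name)
        if node.length is not None:
            label += f":{node.length:.6f}"
        return label

    return render(tree) + ";"
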