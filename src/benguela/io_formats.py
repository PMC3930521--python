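"""Readers, writers and validated containers for the pipeline's data files.

Three kinds of input are handled: an aligned FASTA of haploid mtDNA sequences,
a diploid microsatellite genotype table (GenePop dialect, 2- or 3-digit allele
codes, or a plain TSV with ``a/b`` calls), and a two-level population map
assigning each individual to a sampling site and each site to a region group.
I/O is lossless: gap and ambiguity characters are retained in storage and
downstream statistics decide how to treat them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN-")
MISSING_ALLELE = -1


class FormatError(ValueError):
    """Raised for malformed input files."""


class AlignmentError(FormatError):
    """Raised when sequences of unequal length are presented as an alignment."""


class ValidationError(ValueError):
    """Raised when datasets and the population map are inconsistent."""


@dataclass(frozen=True)
class SequenceAlignment:
    """Equal-length aligned haploid sequences with unique sample ids.

    Sequences are stored uppercase over the alphabet {A, C, G, T, N, -};
    any IUPAC ambiguity code other than N is normalised to N on construction.
    """

    sample_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("duplicate sample ids in alignment")
        if not self.sequences:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        if next(iter(lengths)) == 0:
            raise AlignmentError("zero-length sequences")

    @classmethod
    def from_records(cls, ids: Iterable[str], seqs: Iterable[str]) -> "SequenceAlignment":
        norm = []
        for s in seqs:
            s = s.upper()
            s = "".join(c if c in VALID_BASES else "N" for c in s)
            norm.append(s)
        return cls(tuple(ids), tuple(norm))

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def as_array(self) -> np.ndarray:
        """Alignment as an (n, L) array of single-character strings."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def subset(self, ids: Sequence[str]) -> "SequenceAlignment":
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise ValidationError(f"ids not in alignment: {missing}")
        return SequenceAlignment(
            tuple(ids), tuple(self.sequences[index[i]] for i in ids)
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid allele-size calls: individuals x loci x 2, missing = -1.

    Allele sizes are raw PCR-product sizes in base pairs, as scored by the
    genotyping instrument, not repeat counts. A call is either a full pair of
    positive integers or fully missing.
    """

    sample_ids: tuple[str, ...]
    locus_names: tuple[str, ...]
    calls: np.ndarray  # (n, n_loci, 2) int

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=int)
        if calls.shape != (len(self.sample_ids), len(self.locus_names), 2):
            raise FormatError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(self.sample_ids)} individuals x {len(self.locus_names)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in genotype matrix")
        half_missing = (calls == MISSING_ALLELE).sum(axis=2) == 1
        if half_missing.any():
            raise FormatError("half-missing genotype call (one allele scored)")
        if ((calls != MISSING_ALLELE) & (calls <= 0)).any():
            raise FormatError("allele sizes must be positive integers")
        object.__setattr__(self, "calls", calls)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def missing_mask(self) -> np.ndarray:
        """(n, n_loci) boolean, True where the genotype is missing."""
        return self.calls[:, :, 0] == MISSING_ALLELE

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise ValidationError(f"ids not in genotype matrix: {missing}")
        rows = [index[i] for i in ids]
        return GenotypeMatrix(tuple(ids), self.locus_names, self.calls[rows])


@dataclass(frozen=True)
class PopulationMap:
    """Two-level assignment: individual -> site code, site code -> group label.

    Individual ids are case-sensitive exact-match keys.
    """

    individual_to_site: Mapping[str, str]
    site_to_group: Mapping[str, str]

    def __post_init__(self) -> None:
        unknown = sorted(
            {s for s in self.individual_to_site.values() if s not in self.site_to_group}
        )
        if unknown:
            raise ValidationError(f"sites without a group assignment: {unknown}")
        if not self.site_to_group:
            raise ValidationError("population map has no sites")

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.site_to_group))

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.site_to_group.values()))

    def site_of(self, individual: str) -> str:
        try:
            return self.individual_to_site[individual]
        except KeyError:
            raise ValidationError(f"individual not in population map: {individual!r}")

    def group_of(self, individual: str) -> str:
        return self.site_to_group[self.site_of(individual)]

    def sites_in_group(self, group: str) -> tuple[str, ...]:
        return tuple(s for s, g in self.site_to_group.items() if g == group)

    def individuals_in_site(self, site: str) -> tuple[str, ...]:
        return tuple(i for i, s in self.individual_to_site.items() if s == site)

    def site_labels(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.site_of(i) for i in ids])

    def group_labels(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.group_of(i) for i in ids])

    def validate_ids(self, ids: Iterable[str]) -> None:
        """Raise :class:`ValidationError` naming every unmapped individual."""
        offenders = [i for i in ids if i not in self.individual_to_site]
        if offenders:
            raise ValidationError(
                f"{len(offenders)} individual(s) missing from population map: "
                + ", ".join(offenders[:10])
                + ("..." if len(offenders) > 10 else "")
            )


@dataclass
class ResultBundle:
    """Named result tables plus the metadata needed to reproduce them."""

    tables: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(self.meta, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> SequenceAlignment:
    """Read an aligned FASTA file into a :class:`SequenceAlignment`.

    Lowercase bases are normalised to uppercase; ambiguity codes other than N
    become N. Ragged record lengths raise :class:`AlignmentError`, an empty
    file raises :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return SequenceAlignment.from_records(
        [r.id for r in records], [str(r.seq) for r in records]
    )


def write_fasta(aln: SequenceAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Genotypes: GenePop and TSV dialects
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, dialect: str = "genepop") -> GenotypeMatrix:
    """Read a diploid genotype table.

    ``dialect='genepop'`` parses the classic GenePop layout (title line, locus
    names, ``Pop`` blocks, 2- or 3-digit concatenated allele codes; ``0000`` /
    ``000000`` / blank is missing). ``dialect='tsv'`` expects a header of locus
    names and per-cell ``a/b`` allele pairs (empty or ``./.`` is missing).
    """
    if dialect == "genepop":
        return _read_genepop(path)
    if dialect == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype dialect: {dialect!r}")


def _split_genepop_call(token: str) -> tuple[int, int]:
    if len(token) == 4:
        a, b = int(token[:2]), int(token[2:])
    elif len(token) == 6:
        a, b = int(token[:3]), int(token[3:])
    else:
        raise FormatError(f"genotype token {token!r} is not 4 or 6 digits")
    if a == 0 or b == 0:
        return (MISSING_ALLELE, MISSING_ALLELE)
    return (a, b)


def _read_genepop(path: str | Path) -> GenotypeMatrix:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: too short for a GenePop file")
    body = lines[1:]
    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = body[i].strip()
        if chunk:
            # locus names may be one per line or comma-separated
            locus_names.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not locus_names:
        raise FormatError(f"{path}: no locus names before first 'Pop'")
    sample_ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    for line in body[i:]:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            continue
        if "," not in stripped:
            raise FormatError(f"{path}: genotype line lacks the id separator ',': {stripped!r}")
        ind, geno = stripped.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(locus_names):
            raise FormatError(
                f"{path}: individual {ind.strip()!r} has {len(tokens)} calls, "
                f"expected {len(locus_names)}"
            )
        sample_ids.append(ind.strip())
        rows.append([_split_genepop_call(t) for t in tokens])
    if not sample_ids:
        raise FormatError(f"{path}: no genotype rows")
    return GenotypeMatrix(tuple(sample_ids), tuple(locus_names), np.array(rows))


def _read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: TSV needs a header and at least one row")
    header = lines[0].split("\t")
    locus_names = tuple(header[1:])
    sample_ids, rows = [], []
    for line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"{path}: row {fields[0]!r} has {len(fields) - 1} calls, expected {len(locus_names)}")
        sample_ids.append(fields[0])
        row = []
        for cell in fields[1:]:
            cell = cell.strip()
            if cell in ("", ".", "./.", "NA"):
                row.append((MISSING_ALLELE, MISSING_ALLELE))
            else:
                a, b = cell.split("/")
                row.append((int(a), int(b)))
        rows.append(row)
    return GenotypeMatrix(tuple(sample_ids), locus_names, np.array(rows))


def write_genepop(gm: GenotypeMatrix, popmap: PopulationMap, path: str | Path, digits: int = 3) -> None:
    """Write a GenePop file with one ``Pop`` block per site (map order)."""
    width = digits
    if (gm.calls >= 10 ** width).any():
        raise FormatError(f"allele sizes do not fit in {digits}-digit GenePop coding")
    out = ["genotypes exported by benguela"]
    out.extend(gm.locus_names)
    by_site: dict[str, list[int]] = {s: [] for s in popmap.sites}
    for row, sid in enumerate(gm.sample_ids):
        by_site[popmap.site_of(sid)].append(row)
    for site in popmap.sites:
        if not by_site[site]:
            continue
        out.append("Pop")
        for row in by_site[site]:
            cells = []
            for loc in range(gm.n_loci):
                a, b = gm.calls[row, loc]
                if a == MISSING_ALLELE:
                    cells.append("0" * (2 * width))
                else:
                    cells.append(f"{a:0{width}d}{b:0{width}d}")
            out.append(f"{gm.sample_ids[row]} , " + " ".join(cells))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

def read_popmap(path: str | Path, groups_path: str | Path | None = None) -> PopulationMap:
    """Read a two-level population map.

    The main file holds ``individual<TAB>site`` rows. Site-to-group rows
    (``site<TAB>group``) either follow a line reading ``[groups]`` in the same
    file or live in a separate two-column file passed as ``groups_path``.
    """
    ind_to_site: dict[str, str] = {}
    site_to_group: dict[str, str] = {}
    target = ind_to_site
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower() == "[groups]":
            target = site_to_group
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}: expected two tab-separated columns, got {line!r}")
        target[fields[0]] = fields[1]
    if groups_path is not None:
        for raw in Path(groups_path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{groups_path}: expected two columns, got {line!r}")
            site_to_group[fields[0]] = fields[1]
    if not site_to_group:
        # degenerate but valid: one implicit group containing every site
        site_to_group = {s: "all" for s in dict.fromkeys(ind_to_site.values())}
    return PopulationMap(ind_to_site, site_to_group)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    out = [f"{i}\t{s}" for i, s in popmap.individual_to_site.items()]
    out.append("[groups]")
    out.extend(f"{s}\t{g}" for s, g in popmap.site_to_group.items())
    Path(path).write_text("\n".join(out) + "\n")


def validate_dataset(
    popmap: PopulationMap,
    aln: SequenceAlignment | None = None,
    gm: GenotypeMatrix | None = None,
) -> None:
    """Check that every analysed individual is mapped to a site and group."""
    if aln is not None:
        popmap.validate_ids(aln.sample_ids)
    if gm is not None:
        popmap.validate_ids(gm.sample_ids)
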