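"""Domain types and readers/writers for the standard genomic formats.

All coordinates inside the package are 0-based half-open; the readers for
1-based formats (GTF, VCF) convert at the boundary and the writers convert
back. Soft-masking (lowercase) in FASTA is preserved because the repeat
fraction of a window is defined as its lowercase fraction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

_DNA_RE = re.compile(r"^[ACGTNacgtn]*$")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class RecordError(ValueError):
    """A single record violates an invariant (carries context in message)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """ChIP-seq peak: an interval plus optional summit offset and signal."""

    interval: GenomicInterval
    summit_offset: int | None = None
    signal: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{len(self.interval)}"
            )
        if self.signal < 0:
            raise ValueError("signal must be non-negative")

    @property
    def summit(self) -> int:
        """Absolute summit position; interval midpoint when summit is absent."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.start + len(self.interval) // 2


@dataclass(frozen=True)
class Loop:
    """Chromatin loop with two same-chromosome anchors ordered left/right."""

    anchor_left: GenomicInterval
    anchor_right: GenomicInterval
    support: int = 0

    def __post_init__(self) -> None:
        if self.anchor_left.chrom != self.anchor_right.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor_left.start > self.anchor_right.start:
            raise ValueError("anchors must be ordered left/right by start")
        if self.anchor_left.end > self.anchor_right.start:
            logger.warning(
                "loop anchors overlap: %s [%d,%d) vs [%d,%d)",
                self.anchor_left.chrom,
                self.anchor_left.start,
                self.anchor_left.end,
                self.anchor_right.start,
                self.anchor_right.end,
            )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.anchor_left.chrom, self.anchor_left.start, self.anchor_right.end
        )


@dataclass(frozen=True)
class Gene:
    gene_id: str
    name: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class Variant:
    """Somatic variant in minimal representation, 0-based.

    ``ref``/``alt`` are stripped of shared flanking bases on read; a pure
    deletion has empty ``alt`` and a pure insertion has empty ``ref`` (``pos``
    then points at the first base after the insertion point).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = "."

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for allele in (self.ref, self.alt):
            if not _DNA_RE.match(allele):
                raise ValueError(f"non-DNA allele {allele!r}")

    @property
    def ref_span(self) -> GenomicInterval:
        """Reference footprint; insertions get the 1-bp anchor position."""
        return GenomicInterval(self.chrom, self.pos, self.pos + max(1, len(self.ref)))

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


class Genome(Mapping[str, str]):
    """In-memory genome: chromosome name -> sequence, case preserved."""

    def __init__(self, chroms: dict[str, str]):
        if not chroms:
            raise FormatError("empty genome")
        self._chroms = dict(chroms)

    def __getitem__(self, chrom: str) -> str:
        return self._chroms[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of exactly ``len(interval)`` characters, case preserved."""
        seq = self._chroms[interval.chrom]
        if interval.end > len(seq):
            raise RecordError(
                f"interval [{interval.start},{interval.end}) exceeds "
                f"{interval.chrom} length {len(seq)}"
            )
        return seq[interval.start : interval.end]


def read_fasta(path: str | Path) -> Genome:
    """Read a (possibly soft-masked) FASTA into memory.

    Duplicate chromosome names and empty records are format errors.
    """
    chroms: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chroms:
            raise FormatError(f"duplicate chromosome name {record.id!r}")
        seq = str(record.seq)
        if not seq:
            raise FormatError(f"empty record {record.id!r}")
        chroms[record.id] = seq
    if not chroms:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(chroms)


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read ENCODE narrowPeak (BED6+4); column 10 holds the summit offset."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(
                    f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(fields)}"
                )
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            signal = float(fields[6])
            summit = int(fields[9])
            if end <= start:
                raise RecordError(f"{path}:{lineno}: end <= start")
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    summit_offset=None if summit == -1 else summit,
                    signal=signal,
                    name=name,
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.name}\t0\t.\t{p.signal:g}\t-1\t-1\t{summit}\n"
            )


def read_bedpe(path: str | Path) -> list[Loop]:
    """Read BEDPE loops; anchors are ordered and inter-chromosomal pairs dropped."""
    loops: list[Loop] = []
    n_interchrom = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise RecordError(f"{path}:{lineno}: {exc}") from exc
            if a.chrom != b.chrom:
                n_interchrom += 1
                continue
            if a.start > b.start:
                a, b = b, a
            support = int(fields[7]) if len(fields) > 7 and fields[7].isdigit() else 0
            loops.append(Loop(anchor_left=a, anchor_right=b, support=support))
    if n_interchrom:
        logger.info("dropped %d inter-chromosomal BEDPE records", n_interchrom)
    return loops


def write_bedpe(loops: Iterable[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lo in loops:
            fh.write(
                f"{lo.anchor_left.chrom}\t{lo.anchor_left.start}\t{lo.anchor_left.end}\t"
                f"{lo.anchor_right.chrom}\t{lo.anchor_right.start}\t{lo.anchor_right.end}\t"
                f".\t{lo.support}\n"
            )


def read_gtf_genes(path: str | Path) -> list[Gene]:
    """Extract ``gene`` features from a GTF annotation.

    GTF 1-based inclusive coordinates become 0-based half-open. Rows of other
    feature types are ignored; a missing gene_id or a duplicated one is a
    record error.
    """
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    df = df[df["Feature"] == "gene"]
    genes: list[Gene] = []
    seen: set[str] = set()
    for row in df.itertuples():
        gene_id = getattr(row, "gene_id", None)
        if gene_id is None or (isinstance(gene_id, float)) or gene_id == "":
            raise RecordError(f"gene feature without gene_id in {path}")
        if gene_id in seen:
            raise RecordError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        name = getattr(row, "gene_name", gene_id) or gene_id
        genes.append(
            Gene(
                gene_id=gene_id,
                name=name,
                interval=GenomicInterval(str(row.Chromosome), int(row.Start), int(row.End)),
                strand=str(row.Strand),
            )
        )
    return genes


def write_gtf_genes(genes: Iterable[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name}";'
            fh.write(
                f"{g.interval.chrom}\tctcfkit\tgene\t{g.interval.start + 1}\t"
                f"{g.interval.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def _minimal_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip shared prefix then suffix; returns adjusted (pos, ref, alt)."""
    # shared prefix
    i = 0
    while i < len(ref) and i < len(alt) and ref[i] == alt[i]:
        i += 1
    pos += i
    ref, alt = ref[i:], alt[i:]
    # shared suffix
    j = 0
    while j < len(ref) and j < len(alt) and ref[len(ref) - 1 - j] == alt[len(alt) - 1 - j]:
        j += 1
    if j:
        ref, alt = ref[:-j], alt[:-j]
    return pos, ref, alt


def read_vcf(path: str | Path, genome: Genome | None = None) -> list[Variant]:
    """Read VCF v4.x; multi-allelic records split, alleles minimalized.

    When ``genome`` is supplied every (non-empty) ref allele is verified
    against it. Symbolic alleles are skipped with a logged count.
    """
    from cyvcf2 import VCF

    variants: list[Variant] = []
    n_symbolic = 0
    vcf = VCF(str(path))
    for rec in vcf:
        sample_id = dict(rec.INFO).get("DONOR", ".")
        for alt in rec.ALT:
            if alt.startswith("<") or "[" in alt or "]" in alt or alt == "*":
                n_symbolic += 1
                continue
            pos, ref, alt_min = _minimal_alleles(rec.start, rec.REF.upper(), alt.upper())
            if genome is not None and ref:
                observed = genome.fetch(
                    GenomicInterval(rec.CHROM, pos, pos + len(ref))
                ).upper()
                if observed != ref:
                    raise RecordError(
                        f"ref mismatch at {rec.CHROM}:{pos}: VCF says {ref!r}, "
                        f"genome has {observed!r}"
                    )
            variants.append(
                Variant(chrom=rec.CHROM, pos=pos, ref=ref, alt=alt_min, sample_id=sample_id)
            )
    vcf.close()
    if n_symbolic:
        logger.info("skipped %d symbolic alleles", n_symbolic)
    return variants


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=DONOR,Number=1,Type=String,Description="Sample identifier">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(variants: Iterable[Variant], path: str | Path, genome: Genome | None = None) -> None:
    """Write variants as VCF; indels regain an anchor base from ``genome``."""
    with open(path, "w") as fh:
        header = VCF_HEADER
        if genome is not None:
            contigs = "".join(
                f"##contig=<ID={c},length={len(genome[c])}>\n" for c in genome
            )
            header = header.replace("#CHROM", contigs + "#CHROM")
        fh.write(header)
        for v in variants:
            pos, ref, alt = v.pos, v.ref, v.alt
            if not ref or not alt:  # indel: prepend the VCF anchor base
                if genome is None:
                    raise ValueError("writing indels requires the genome for the anchor base")
                anchor = genome.fetch(GenomicInterval(v.chrom, pos - 1, pos)).upper()
                pos, ref, alt = pos - 1, anchor + ref, anchor + alt
            info = "." if v.sample_id == "." else f"DONOR={v.sample_id}"
            fh.write(f"{v.chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Plain-text one-gene-symbol-per-line list, uppercased for matching."""
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
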