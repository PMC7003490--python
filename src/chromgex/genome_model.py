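"""Domain types and file readers/writers for the gene-regulation data model.

All coordinates are held internally as 0-based half-open intervals
``[start, end)``.  GTF input (1-based, inclusive) is converted on read;
BED-family formats already use the internal convention and pass through.

Chromosome naming ("chr1" vs "1") is normalized on read when a style is
requested; mixing styles across inputs is detected downstream and raised as
an error rather than silently producing empty overlaps.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Gene",
    "Peak",
    "ChromHMMSegment",
    "ChromatinLoop",
    "PSEM",
    "read_gene_annotation",
    "read_peaks",
    "read_loops",
    "read_chromhmm",
    "read_psems",
    "read_expression",
    "write_gene_annotation",
    "write_peaks",
    "write_loops",
    "write_chromhmm",
    "write_psems",
    "write_expression",
    "most_5prime_tss",
    "normalize_chrom",
    "detect_chrom_style",
    "check_chrom_consistency",
]


class ParseError(ValueError):
    """A malformed record in an input file (carries the line number)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Gene:
    """A gene with its transcript 5' ends.

    ``transcript_starts`` holds, for every transcript, the coordinate of its
    5' end under the strand convention: the transcript start for ``+`` genes
    and the transcript end for ``-`` genes.  The most-5' TSS is the minimum
    on ``+`` and the maximum on ``-``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    gene_type: str = "protein_coding"
    transcript_starts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        return most_5prime_tss(self)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def most_5prime_tss(gene: Gene) -> int:
    """The transcript start furthest upstream in the gene's reading direction."""
    starts = gene.transcript_starts
    if not starts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    return min(starts) if gene.strand == "+" else max(starts)


@dataclass(frozen=True)
class Peak:
    """An open-chromatin (e.g. DNase1-seq) peak with accessibility signal."""

    interval: GenomicInterval
    signal: float = 0.0
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"negative signal for peak {self.interval}")

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def center(self) -> float:
        return self.interval.center


@dataclass(frozen=True)
class ChromHMMSegment:
    """A chromatin-state segment; adjacent same-state segments are merged on read."""

    interval: GenomicInterval
    state: str


@dataclass(frozen=True)
class ChromatinLoop:
    """An intra-chromosomal chromatin contact between two anchor intervals."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    resolution: str = "All"
    pet_count: int | None = None
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("inter-chromosomal loop")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def anchor_distance(self) -> float:
        return abs(self.anchor1.center - self.anchor2.center)


@dataclass(frozen=True)
class PSEM:
    """Position-specific energy matrix describing a TF's binding preference.

    ``matrix`` has shape (length, 4) with columns A, C, G, T holding
    non-negative mismatch energies; the consensus base of a position has
    energy 0.
    """

    tf_name: str
    matrix: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.matrix) < 1:
            raise ValueError("PSEM needs at least one position")
        for row in self.matrix:
            if len(row) != 4:
                raise ValueError("every PSEM position needs 4 nucleotide entries")

    @property
    def length(self) -> int:
        return len(self.matrix)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)


# ---------------------------------------------------------------------------
# chromosome-name normalization
# ---------------------------------------------------------------------------


def normalize_chrom(name: str, style: str | None) -> str:
    """Convert a chromosome name to the requested style ('chr', 'plain', None)."""
    if style is None:
        return name
    bare = name[3:] if name.lower().startswith("chr") else name
    if style == "plain":
        return bare
    if style == "chr":
        return f"chr{bare}"
    raise ValueError(f"unknown chromosome style {style!r}")


def detect_chrom_style(names: Iterable[str]) -> str:
    """Return 'chr', 'plain' or 'mixed' for a collection of chromosome names."""
    styles = {("chr" if n.lower().startswith("chr") else "plain") for n in names}
    if len(styles) > 1:
        return "mixed"
    return styles.pop() if styles else "plain"


def check_chrom_consistency(**named_collections: Iterable[str]) -> None:
    """Raise if the inputs use different chromosome naming styles.

    Mismatched styles would make every overlap silently empty, which is the
    worst possible failure mode for an interval pipeline.
    """
    seen: dict[str, str] = {}
    for label, names in named_collections.items():
        names = list(names)
        if not names:
            continue
        seen[label] = detect_chrom_style(names)
    styles = set(seen.values())
    if "mixed" in styles or len(styles) > 1:
        raise ValueError(
            "chromosome naming styles differ across inputs: "
            + ", ".join(f"{k}={v}" for k, v in sorted(seen.items()))
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(s: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(s))


def read_gene_annotation(
    path: str | Path,
    biotype_filter: str | None = "protein_coding",
    chrom_style: str | None = None,
) -> list[Gene]:
    """Read genes (and their transcript 5' ends) from a GTF file.

    GTF coordinates are 1-based inclusive; they are shifted to the internal
    0-based half-open convention here.  ``biotype_filter`` keeps only genes
    whose ``gene_type``/``gene_biotype`` attribute matches; ``None`` keeps
    everything.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(parts)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = parts[:9]
            if feature not in ("gene", "transcript"):
                continue
            try:
                start = int(start_s) - 1  # GTF 1-based inclusive -> 0-based half-open
                end = int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _parse_gtf_attributes(attrs_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            chrom = normalize_chrom(chrom, chrom_style)
            rec = genes.setdefault(
                gene_id,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "gene_type": attrs.get("gene_type", attrs.get("gene_biotype", "")),
                    "tss": [],
                },
            )
            if feature == "gene":
                rec["start"], rec["end"] = start, end
                bt = attrs.get("gene_type", attrs.get("gene_biotype", ""))
                if bt:
                    rec["gene_type"] = bt
            else:  # transcript: record its 5' end under the strand convention
                rec["tss"].append(start if strand == "+" else end)
                rec["start"] = min(rec["start"], start)
                rec["end"] = max(rec["end"], end)

    out: list[Gene] = []
    for gene_id, rec in genes.items():
        if biotype_filter is not None and rec["gene_type"] != biotype_filter:
            continue
        tss = tuple(rec["tss"]) or (
            (rec["start"],) if rec["strand"] == "+" else (rec["end"],)
        )
        out.append(
            Gene(
                gene_id=gene_id,
                chrom=rec["chrom"],
                strand=rec["strand"],
                start=rec["start"],
                end=rec["end"],
                gene_type=rec["gene_type"],
                transcript_starts=tss,
            )
        )
    if not out:
        warnings.warn(f"no genes retained from {path} (biotype_filter={biotype_filter!r})")
    return sorted(out, key=lambda g: (g.chrom, g.start, g.gene_id))


def read_peaks(
    path: str | Path,
    signal_column: int = 6,
    chrom_style: str | None = None,
) -> list[Peak]:
    """Read peaks from BED / narrowPeak.

    ``signal_column`` is the 0-based index of the per-peak signal column;
    the narrowPeak ``signalValue`` (column 7, index 6) is the default.
    Records with ``end <= start`` are rejected and counted; if any signal
    value is present but non-numeric, a parse error is raised.
    """
    peaks: list[Peak] = []
    rejected = 0
    missing_signal = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = normalize_chrom(parts[0], chrom_style)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                rejected += 1
                continue
            name = parts[3] if len(parts) > 3 else "."
            score = 0.0
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            if len(parts) > signal_column:
                try:
                    signal = float(parts[signal_column])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric signal in column {signal_column + 1}"
                    ) from exc
            else:
                signal = 0.0
                missing_signal += 1
            peaks.append(Peak(GenomicInterval(chrom, start, end), signal, score, name))
    if missing_signal:
        warnings.warn(
            f"{missing_signal} peak(s) in {path} lack a signal column; signal set to 0"
        )
    if rejected:
        warnings.warn(f"{rejected} malformed peak record(s) in {path} rejected")
    return peaks


def read_loops(
    path: str | Path,
    resolution_filter: str = "All",
    pet_min: int = 0,
    q_max: float = 1.0,
    chrom_style: str | None = None,
    pet_column: int = 7,
    q_column: int = 8,
    resolution_column: int = 6,
) -> list[ChromatinLoop]:
    """Read chromatin loops from a BEDPE-dialect file.

    Columns 1-6 are the two anchors; optional extra columns carry the
    resolution label, the PET count and the interaction q-value (0-based
    indices configurable).  Inter-chromosomal records are excluded (and
    counted); ``resolution_filter="All"`` keeps every resolution, otherwise
    the label must match exactly.
    """
    loops: list[ChromatinLoop] = []
    inter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 BEDPE columns")
            c1 = normalize_chrom(parts[0], chrom_style)
            c2 = normalize_chrom(parts[3], chrom_style)
            try:
                s1, e1, s2, e2 = int(parts[1]), int(parts[2]), int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if c1 != c2:
                inter += 1
                continue
            resolution = (
                parts[resolution_column]
                if len(parts) > resolution_column and parts[resolution_column] not in (".", "")
                else "All"
            )
            pet: int | None = None
            if len(parts) > pet_column and parts[pet_column] not in (".", ""):
                pet = int(float(parts[pet_column]))
            qv: float | None = None
            if len(parts) > q_column and parts[q_column] not in (".", ""):
                qv = float(parts[q_column])
            if pet_min > 0:
                if pet is None:
                    raise ParseError(
                        f"{path}:{lineno}: pet_min={pet_min} requires a PET column"
                    )
                if pet < pet_min:
                    continue
            if qv is not None and qv > q_max:
                continue
            if resolution_filter != "All" and resolution != resolution_filter:
                continue
            loops.append(
                ChromatinLoop(
                    GenomicInterval(c1, s1, e1),
                    GenomicInterval(c2, s2, e2),
                    resolution=resolution,
                    pet_count=pet,
                    q_value=qv,
                )
            )
    if inter:
        warnings.warn(f"{inter} inter-chromosomal loop(s) in {path} excluded")
    return loops


def read_chromhmm(
    path: str | Path,
    kept_states: set[str] | None = None,
    chrom_style: str | None = None,
) -> list[ChromHMMSegment]:
    """Read a chromatin-state segmentation (BED4), keep selected states and
    merge adjacent (book-ended or overlapping) same-state segments."""
    raw: list[ChromHMMSegment] = []
    seen_states: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 BED columns (state label)")
            chrom = normalize_chrom(parts[0], chrom_style)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            state = parts[3]
            seen_states.add(state)
            if kept_states is not None and state not in kept_states:
                continue
            raw.append(ChromHMMSegment(GenomicInterval(chrom, start, end), state))
    if kept_states is not None and not (kept_states & seen_states) and seen_states:
        raise ParseError(
            f"none of the requested states {sorted(kept_states)} occur in {path}; "
            f"labels seen: {sorted(seen_states)}"
        )
    return merge_adjacent_segments(raw)


def merge_adjacent_segments(segments: Sequence[ChromHMMSegment]) -> list[ChromHMMSegment]:
    """Merge touching/overlapping segments of identical state on one chromosome."""
    ordered = sorted(segments, key=lambda s: (s.interval.chrom, s.state, s.interval.start))
    merged: list[ChromHMMSegment] = []
    for seg in ordered:
        if (
            merged
            and merged[-1].state == seg.state
            and merged[-1].interval.chrom == seg.interval.chrom
            and seg.interval.start <= merged[-1].interval.end
        ):
            prev = merged.pop()
            merged.append(
                ChromHMMSegment(
                    GenomicInterval(
                        prev.interval.chrom,
                        prev.interval.start,
                        max(prev.interval.end, seg.interval.end),
                    ),
                    prev.state,
                )
            )
        else:
            merged.append(seg)
    merged.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return merged


def read_psems(path: str | Path) -> list[PSEM]:
    """Read PSEMs from text: one ``>NAME`` header per matrix followed by one
    whitespace-separated A C G T energy row per motif position."""
    psems: list[PSEM] = []
    name: str | None = None
    rows: list[tuple[float, float, float, float]] = []
    seen: dict[str, int] = {}

    def flush(lineno: int) -> None:
        nonlocal name, rows
        if name is None:
            return
        if not rows:
            raise ParseError(f"{path}:{lineno}: PSEM {name!r} has no positions")
        final = name
        if final in seen:
            seen[final] += 1
            final = f"{final}.{seen[name]}"
            warnings.warn(f"duplicate PSEM name {name!r}; renamed to {final!r}")
        else:
            seen[final] = 0
        psems.append(PSEM(final, tuple(rows)))
        name, rows = None, []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                name = line[1:].split()[0]
                continue
            vals = line.split()
            if len(vals) != 4:
                raise ParseError(f"{path}:{lineno}: PSEM row needs 4 values, got {len(vals)}")
            try:
                rows.append(tuple(float(v) for v in vals))  # type: ignore[arg-type]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric PSEM entry") from exc
        flush(lineno)
    if not psems:
        warnings.warn(f"no PSEMs found in {path}")
    return psems


def read_expression(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV of gene_id -> non-negative expression estimate."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 TSV columns")
            if lineno == 1 and parts[0].lower() in ("gene", "gene_id", "geneid"):
                continue
            try:
                value = float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric expression value") from exc
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative expression value")
            table[parts[0]] = value
    return table


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers above)
# ---------------------------------------------------------------------------


def write_gene_annotation(genes: Iterable[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.gene_type}";'
            fh.write(
                f"{g.chrom}\tchromgex\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tss in g.transcript_starts:
                if g.strand == "+":
                    t_start, t_end = tss, g.end
                else:
                    t_start, t_end = g.start, tss
                fh.write(
                    f"{g.chrom}\tchromgex\ttranscript\t{t_start + 1}\t{t_end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as narrowPeak (signal in column 7)."""
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start)):
            i = p.interval
            fh.write(
                f"{i.chrom}\t{i.start}\t{i.end}\t{p.name}\t{p.score:g}\t.\t"
                f"{p.signal:g}\t-1\t-1\t-1\n"
            )


def write_loops(loops: Iterable[ChromatinLoop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchor1, lp.anchor2
            pet = "." if lp.pet_count is None else str(lp.pet_count)
            qv = "." if lp.q_value is None else f"{lp.q_value:g}"
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{lp.resolution}\t{pet}\t{qv}\n"
            )


def write_chromhmm(segments: Iterable[ChromHMMSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            i = s.interval
            fh.write(f"{i.chrom}\t{i.start}\t{i.end}\t{s.state}\n")


def write_psems(psems: Iterable[PSEM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in psems:
            fh.write(f">{m.tf_name}\n")
            for row in m.matrix:
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


def write_expression(table: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\texpression\n")
        for gene_id, value in table.items():
            fh.write(f"{gene_id}\t{value:.6g}\n")
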