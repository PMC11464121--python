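"""Probe-to-retroelement annotation.

Methylation arrays interrogate single cytosines at known genomic
coordinates.  A probe belongs to the retroelement CpG universe when its
coordinate falls inside an annotated retroelement locus (a HERV
transcriptional unit, a LINE, an LTR or SINE remnant, ...).  Overlap is by
point containment, ``start <= pos <= end`` on the same chromosome, strand
ignored: methylation at a CpG is symmetric across strands and locus
boundaries are orders of magnitude wider than the 2-bp dinucleotide.

Coordinates are 1-based inclusive throughout this module; conversions from
0-based formats happen at I/O time (:mod:`retroclock.io_formats`).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .exceptions import ChromosomeNamingError, ValidationError

logger = logging.getLogger(__name__)

#: Closed vocabulary of repeat classes.  Anything else maps to "Unknown".
REPEAT_CLASSES = ("HERV", "LINE", "LTR", "SINE", "DNA", "Unknown")

_CLASS_ALIASES = {
    "HERV": "HERV",
    "ERV": "HERV",
    "ERVL": "HERV",
    "LINE": "LINE",
    "L1": "LINE",
    "LTR": "LTR",
    "SINE": "SINE",
    "DNA": "DNA",
    "UNKNOWN": "Unknown",
}


def normalize_repeat_class(value: str | None) -> str:
    """Map a free-text repeat class label onto the closed vocabulary.

    RepeatMasker-style compound labels ("LINE/L1") are resolved by their
    top-level class; unrecognized labels become "Unknown".
    """
    if value is None:
        return "Unknown"
    head = str(value).split("/")[0].strip()
    return _CLASS_ALIASES.get(head.upper(), "Unknown")


@dataclass(frozen=True)
class RetroLocus:
    """One annotated retroelement interval (1-based inclusive)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    family: str = "Unknown"
    repeat_class: str = "Unknown"

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ValidationError("locus_id must be non-empty")
        if self.start > self.end:
            raise ValidationError(
                f"locus {self.locus_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValidationError(f"locus {self.locus_id}: start must be >= 1")
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValidationError(
                f"locus {self.locus_id}: class {self.repeat_class!r} not in "
                f"{REPEAT_CLASSES}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"locus {self.locus_id}: bad strand {self.strand!r}")


@dataclass
class ProbeAnnotation:
    """All retroelement loci containing one probe's cytosine."""

    probe_id: str
    hits: list[tuple[str, str, str]] = field(default_factory=list)
    # each hit is (locus_id, family, repeat_class), deduplicated by locus_id

    @property
    def is_retro(self) -> bool:
        return len(self.hits) > 0

    @property
    def classes(self) -> set[str]:
        return {c for _, _, c in self.hits}


class IntervalIndex:
    """Point-queryable index over retroelement loci, one tree per chromosome."""

    def __init__(self, loci: Iterable[RetroLocus]):
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._n = 0
        seen: set[str] = set()
        for locus in loci:
            if locus.locus_id in seen:
                raise ValidationError(f"duplicate locus_id {locus.locus_id!r}")
            seen.add(locus.locus_id)
            # intervaltree is half-open; store [start, end + 1)
            self._trees[locus.chrom].addi(locus.start, locus.end + 1, locus)
            self._n += 1

    def __len__(self) -> int:
        return self._n

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)

    def query(self, chrom: str, pos: int) -> list[RetroLocus]:
        """All loci containing position ``pos`` (1-based) on ``chrom``,
        sorted by locus_id for deterministic output."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.at(pos)), key=lambda l: l.locus_id)


def build_interval_index(loci: Sequence[RetroLocus]) -> IntervalIndex:
    """Build the point-query index used by :func:`annotate_probes`."""
    return IntervalIndex(loci)


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def annotate_probes(
    probes: Sequence,
    index: IntervalIndex,
    *,
    chr_alias: bool = False,
) -> list[ProbeAnnotation]:
    """Annotate each probe with the retroelement loci containing it.

    A probe hits a locus iff ``start <= pos <= end`` on the same chromosome.
    If the probe and locus chromosome name sets are disjoint but match after
    stripping the "chr" prefix, the two inputs use different naming
    conventions; that is a hard error unless ``chr_alias=True``, in which
    case both sides are normalized by stripping the prefix.  Silent
    normalization is never performed.
    """
    probe_chroms = {p.chrom for p in probes}
    if probe_chroms and index.chroms and not chr_alias:
        if not (probe_chroms & index.chroms):
            stripped_p = {_strip_chr(c) for c in probe_chroms}
            stripped_l = {_strip_chr(c) for c in index.chroms}
            if stripped_p & stripped_l:
                raise ChromosomeNamingError(
                    "probe and annotation chromosome names do not overlap but "
                    "agree after removing the 'chr' prefix; pass chr_alias=True "
                    "to normalize"
                )

    alias = _strip_chr if chr_alias else (lambda c: c)
    trees: dict[str, list] = {}
    if chr_alias:
        # rebuild a lookup keyed by stripped names
        merged: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for chrom, tree in index._trees.items():
            merged[_strip_chr(chrom)] |= tree
        lookup = merged
    else:
        lookup = index._trees

    out: list[ProbeAnnotation] = []
    for probe in probes:
        tree = lookup.get(alias(probe.chrom))
        if tree is None:
            out.append(ProbeAnnotation(probe.probe_id))
            continue
        hits = sorted((iv.data for iv in tree.at(probe.pos)), key=lambda l: l.locus_id)
        seen: set[str] = set()
        dedup = []
        for locus in hits:
            if locus.locus_id not in seen:
                seen.add(locus.locus_id)
                dedup.append((locus.locus_id, locus.family, locus.repeat_class))
        out.append(ProbeAnnotation(probe.probe_id, dedup))

    n_hit = sum(a.is_retro for a in out)
    frac = n_hit / len(out) if out else 0.0
    logger.info(
        "annotated %d / %d probes (%.2f%%) to retroelement loci",
        n_hit, len(out), 100 * frac,
    )
    return out


@dataclass
class AnnotationSummary:
    """Per-class and per-family probe counts.

    A probe hitting loci of two classes counts once in each class but once
    in ``n_annotated`` (distinct annotated probes).
    """

    class_counts: dict[str, int]
    family_counts: dict[str, int]
    n_annotated: int
    n_probes: int

    @property
    def fraction_annotated(self) -> float:
        return self.n_annotated / self.n_probes if self.n_probes else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"level": "class", "name": k, "n_probes": v}
            for k, v in sorted(self.class_counts.items())
        ] + [
            {"level": "family", "name": k, "n_probes": v}
            for k, v in sorted(self.family_counts.items())
        ]
        rows.append({"level": "total", "name": "annotated", "n_probes": self.n_annotated})
        return pd.DataFrame(rows, columns=["level", "name", "n_probes"])


def summarize_annotation(annotations: Sequence[ProbeAnnotation]) -> AnnotationSummary:
    """Count annotated probes per repeat class and per family."""
    class_counts: dict[str, int] = defaultdict(int)
    family_counts: dict[str, int] = defaultdict(int)
    n_annotated = 0
    for ann in annotations:
        if not ann.is_retro:
            continue
        n_annotated += 1
        for cls in ann.classes:
            class_counts[cls] += 1
        for fam in {f for _, f, _ in ann.hits}:
            family_counts[fam] += 1
    return AnnotationSummary(
        dict(class_counts), dict(family_counts), n_annotated, len(annotations)
    )


def select_retro_probes(
    beta,
    annotations: Sequence[ProbeAnnotation],
    classes: set[str] | None = None,
):
    """Restrict a beta matrix to annotated retroelement probes.

    Parameters
    ----------
    beta
        :class:`~retroclock.io_formats.BetaMatrix` (probes x samples).
    annotations
        Output of :func:`annotate_probes`.
    classes
        Repeat classes to keep (subset of :data:`REPEAT_CLASSES`); default
        all.  A probe is kept when it is annotated and at least one of its
        hit classes intersects ``classes``.

    Returns
    -------
    BetaMatrix
        Row subset, original row order preserved.

    Raises
    ------
    ValidationError
        If ``classes`` contains an unknown label or no probe is retained
        (clock training would be impossible).
    """
    from .io_formats import BetaMatrix  # local import: io_formats imports us

    if classes is not None:
        bad = set(classes) - set(REPEAT_CLASSES)
        if bad:
            raise ValidationError(f"unknown repeat classes: {sorted(bad)}")
        wanted = set(classes)
    else:
        wanted = set(REPEAT_CLASSES)

    keep_ids = {
        a.probe_id for a in annotations if a.is_retro and (a.classes & wanted)
    }
    mask = [pid in keep_ids for pid in beta.probe_ids]
    n_kept = sum(mask)
    if n_kept == 0:
        raise ValidationError(
            "no probes retained after retroelement filtering "
            f"(classes={sorted(wanted)}); cannot train a clock"
        )
    logger.info("retained %d / %d probes after retroelement filtering",
                n_kept, len(mask))
    return BetaMatrix(beta.data.loc[mask])
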