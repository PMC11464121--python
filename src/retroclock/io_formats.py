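"""Readers and writers for every tabular / genomic-interval format the
pipeline touches, with strict validation.

Conventions
-----------
* Genomic coordinates are 1-based inclusive internally; BED input (0-based
  half-open) is converted on read and back on write.
* Beta matrices are probes x samples (rows = probes), the methylation
  community convention.  Transposed input is never auto-detected silently.
* Missing values are accepted as ``NA``, ``NaN`` or the empty string on
  read and written as ``NA``.
* Parsers never silently coerce: every dropped row is counted in the
  returned :class:`ParseReport`.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, FormatError, ValidationError
from .retro_annotation import RetroLocus, normalize_repeat_class

MISSING_TOKENS = ("NA", "NaN", "")

PLATFORMS = ("EPICv1", "EPICv2", "450K", "Mammal40", "custom")

#: default header aliases for manifest CSVs (Illumina manifests use
#: IlmnID / CHR / MAPINFO)
MANIFEST_ALIASES: dict[str, tuple[str, ...]] = {
    "probe_id": ("probe_id", "IlmnID", "Name", "probeID", "CGid"),
    "chrom": ("chrom", "CHR", "chr", "chromosome", "seqnames"),
    "pos": ("pos", "MAPINFO", "position", "CpG_beg"),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeRecord:
    """One array probe and the 1-based coordinate of its interrogated
    cytosine."""

    probe_id: str
    chrom: str
    pos: int
    platform: str = "custom"

    def __post_init__(self) -> None:
        if not self.probe_id:
            raise ValidationError("probe_id must be non-empty")
        if not self.chrom:
            raise ValidationError(f"probe {self.probe_id}: chrom must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"probe {self.probe_id}: pos must be >= 1")
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"probe {self.probe_id}: platform {self.platform!r} not in {PLATFORMS}"
            )


class BetaMatrix:
    """Beta values (fraction methylated, in [0, 1]) as probes x samples.

    Thin wrapper over a float ``pandas.DataFrame`` whose index is probe ids
    and whose columns are sample ids; construction validates uniqueness and
    the [0, 1] range (NaN allowed for missing).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = data.to_numpy(dtype=float, copy=False)
        bad = np.nonzero((values < 0) | (values > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValidationError(
                f"beta value {values[i, j]!r} outside [0, 1] at probe "
                f"{data.index[i]!r}, sample {data.columns[j]!r}"
            )
        self.data = data.astype(float)
        self.data.index.name = "probe_id"
        self.data.columns.name = None

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise ValidationError(f"probes not in matrix: {missing[:5]}")
        return BetaMatrix(self.data.loc[list(probe_ids)])

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        return BetaMatrix(self.data[list(sample_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, BetaMatrix) and self.data.equals(other.data)


@dataclass
class ParseReport:
    """What a reader kept, dropped and why."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped_missing: int = 0
    dropped_lines: list[int] = field(default_factory=list)  # 1-based file lines


# ---------------------------------------------------------------------------
# probe manifests
# ---------------------------------------------------------------------------

def _resolve_column(columns: Sequence[str], canonical: str,
                    aliases: Mapping[str, tuple[str, ...]]) -> str:
    for name in aliases[canonical]:
        for col in columns:
            if col.strip().lower() == name.lower():
                return col
    raise FormatError(
        f"manifest is missing a {canonical!r} column "
        f"(accepted names: {', '.join(aliases[canonical])})"
    )


def read_manifest(
    path,
    platform_tag: str = "custom",
    aliases: Mapping[str, tuple[str, ...]] | None = None,
) -> tuple[list[ProbeRecord], ParseReport]:
    """Read a probe manifest CSV into validated :class:`ProbeRecord`s.

    Rows with a missing chromosome or coordinate are dropped and counted in
    the report; a non-integer coordinate or duplicate probe id is an error.
    """
    alias_map = dict(MANIFEST_ALIASES)
    if aliases:
        alias_map.update(aliases)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    id_col = _resolve_column(df.columns, "probe_id", alias_map)
    chrom_col = _resolve_column(df.columns, "chrom", alias_map)
    pos_col = _resolve_column(df.columns, "pos", alias_map)

    report = ParseReport(n_rows=len(df))
    records: list[ProbeRecord] = []
    seen: dict[str, int] = {}
    dup: list[str] = []
    ids = df[id_col].astype(str).str.strip()
    chroms = df[chrom_col].astype(str).str.strip()
    positions = df[pos_col].astype(str).str.strip()
    for i in range(len(df)):
        line_no = i + 2  # header is line 1
        pid = ids.iat[i]
        chrom = chroms.iat[i]
        pos_raw = positions.iat[i]
        if chrom in MISSING_TOKENS or pos_raw in MISSING_TOKENS:
            report.n_dropped_missing += 1
            report.dropped_lines.append(line_no)
            continue
        try:
            pos_f = float(pos_raw)
            if not pos_f.is_integer():
                raise ValueError
            pos = int(pos_f)
        except ValueError:
            raise FormatError(
                f"line {line_no}: position {pos_raw!r} is not an integer"
            ) from None
        if pid in seen:
            dup.append(pid)
            continue
        seen[pid] = line_no
        records.append(ProbeRecord(pid, chrom, pos, platform_tag))
    if dup:
        raise ValidationError(f"duplicate probe ids in manifest: {sorted(set(dup))}")
    report.n_kept = len(records)
    return records, report


# ---------------------------------------------------------------------------
# retroelement annotations (GTF / BED6 / CSV)
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, val = chunk.partition(" ")
            out[key.strip()] = val.strip().strip('"')
    return out


def read_annotation(
    path,
    dialect: str,
    *,
    locus_field: str | None = None,
    family_field: str | None = None,
    class_field: str | None = None,
    default_class: str = "Unknown",
) -> list[RetroLocus]:
    """Read a retroelement locus annotation into 1-based inclusive
    :class:`~retroclock.retro_annotation.RetroLocus` records.

    ``dialect`` is one of ``GTF`` (1-based inclusive, family/class from the
    attribute column), ``BED6`` (0-based half-open, converted on read) or
    ``CSV`` (columns locus, chrom, start, end, family, class; 1-based).
    """
    dialect = dialect.upper()
    if dialect not in ("GTF", "BED6", "CSV"):
        raise FormatError(f"unknown annotation dialect {dialect!r}")

    loci: list[RetroLocus] = []
    if dialect == "GTF":
        locus_keys = (locus_field,) if locus_field else ("locus_id", "locus", "gene_id")
        family_keys = (family_field,) if family_field else ("family", "repFamily")
        class_keys = (class_field,) if class_field else ("class", "repClass")
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9:
                    raise FormatError(
                        f"line {line_no}: GTF requires 9 tab-separated fields, "
                        f"got {len(parts)}"
                    )
                chrom, _src, _feat, start_s, end_s, _score, strand, _frame, attr = parts
                attrs = _parse_gtf_attributes(attr)
                locus_id = next((attrs[k] for k in locus_keys if k in attrs), None)
                if locus_id is None:
                    raise FormatError(
                        f"line {line_no}: no locus identifier attribute "
                        f"(tried {locus_keys})"
                    )
                family = next((attrs[k] for k in family_keys if k in attrs), "Unknown")
                cls = next((attrs[k] for k in class_keys if k in attrs), default_class)
                start, end = int(start_s), int(end_s)
                if start > end:
                    raise FormatError(f"line {line_no}: start {start} > end {end}")
                loci.append(RetroLocus(
                    locus_id, chrom, start, end,
                    strand if strand in ("+", "-") else ".",
                    family, normalize_repeat_class(cls),
                ))
    elif dialect == "BED6":
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise FormatError(
                        f"line {line_no}: BED6 requires >= 4 fields, got {len(parts)}"
                    )
                chrom, start_s, end_s, name = parts[:4]
                strand = parts[5] if len(parts) >= 6 else "."
                bed_start, bed_end = int(start_s), int(end_s)
                start, end = bed_start + 1, bed_end  # half-open -> inclusive
                if start > end:
                    raise FormatError(
                        f"line {line_no}: empty or inverted interval "
                        f"[{bed_start}, {bed_end})"
                    )
                loci.append(RetroLocus(
                    name, chrom, start, end,
                    strand if strand in ("+", "-") else ".",
                    "Unknown", normalize_repeat_class(default_class),
                ))
    else:  # CSV
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        cols = {c.lower(): c for c in df.columns}
        required = ("locus", "chrom", "start", "end")
        missing = [c for c in required if c not in cols]
        if missing:
            raise FormatError(f"CSV annotation missing columns: {missing}")
        fam_col = cols.get((family_field or "family").lower())
        cls_col = cols.get((class_field or "class").lower())
        strand_col = cols.get("strand")
        for i in range(len(df)):
            start, end = int(df.iat[i, df.columns.get_loc(cols["start"])]), \
                int(df.iat[i, df.columns.get_loc(cols["end"])])
            if start > end:
                raise FormatError(f"row {i + 2}: start {start} > end {end}")
            loci.append(RetroLocus(
                df.iat[i, df.columns.get_loc(cols["locus"])],
                df.iat[i, df.columns.get_loc(cols["chrom"])],
                start, end,
                df.iat[i, df.columns.get_loc(strand_col)] if strand_col else ".",
                df.iat[i, df.columns.get_loc(fam_col)] if fam_col else "Unknown",
                normalize_repeat_class(
                    df.iat[i, df.columns.get_loc(cls_col)] if cls_col else default_class
                ),
            ))
    return loci


def write_annotation_bed(loci: Iterable[RetroLocus], path) -> None:
    """Write loci as BED6 (converting back to 0-based half-open)."""
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\t"
                f"{locus.locus_id}\t0\t{locus.strand if locus.strand != '.' else '.'}\n"
            )


# ---------------------------------------------------------------------------
# beta / count matrices
# ---------------------------------------------------------------------------

def _check_rectangular(path, sep: str = "\t") -> None:
    with open(path) as fh:
        header = fh.readline()
        n_fields = header.rstrip("\n").count(sep) + 1
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            n = line.rstrip("\n").count(sep) + 1
            if n != n_fields:
                raise FormatError(
                    f"line {line_no}: expected {n_fields} fields, got {n} (ragged row)"
                )


def read_beta_matrix(path) -> BetaMatrix:
    """Read a probes x samples TSV of beta values.

    First column is the probe id; missing cells may be NA/NaN/empty.  Any
    value outside [0, 1] is rejected naming the probe and sample.
    """
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    df = df.apply(lambda s: s.str.strip())
    df = df.mask(df.isin(MISSING_TOKENS))
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric beta value: {exc}") from None
    df.index = df.index.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.data.to_csv(path, sep="\t", na_rep="NA")


def read_count_matrix(path) -> pd.DataFrame:
    """Read a loci x samples TSV of non-negative integer counts."""
    _check_rectangular(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise ValidationError(
            f"negative count at locus {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if not np.allclose(values, np.round(values)):
        raise ValidationError("count matrix contains non-integer values")
    return df.astype(int)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

METADATA_OPTIONAL = ("donor_id", "group", "species", "tissue", "timepoint",
                     "replicate_of")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read sample metadata CSV, indexed by sample_id.

    Requires ``sample_id``; ``age`` (years, >= 0) plus the optional
    columns donor_id, group, species, tissue, timepoint, replicate_of are
    preserved when present.
    """
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("metadata must contain a sample_id column")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in metadata: {dups[:5]}")
    df = df.set_index("sample_id")
    if "age" in df.columns:
        ages = pd.to_numeric(df["age"], errors="raise")
        if (ages.dropna() < 0).any():
            bad = df.index[ages < 0].tolist()
            raise ValidationError(f"negative ages for samples: {bad[:5]}")
        df["age"] = ages
    return df


# ---------------------------------------------------------------------------
# clock model serialization (CSV of terms + JSON sidecar)
# ---------------------------------------------------------------------------

INTERCEPT_TERM = "(Intercept)"


def sidecar_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_clock_model(model, path) -> None:
    """Write a clock as a coefficient CSV plus a JSON sidecar.

    The CSV has columns (term, coefficient, training_mean) with the first
    row ``(Intercept)``; coefficients are written at full float precision so
    the round trip is exact.  The sidecar records name, platform, transform,
    n_train, seed and the CpG list for consistency checking.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["term", "coefficient", "training_mean"])
        writer.writerow([INTERCEPT_TERM, repr(float(model.intercept)), ""])
        means = model.training_means or {}
        for term, coef in model.coefficients.items():
            mean = means.get(term)
            writer.writerow([
                term, repr(float(coef)),
                "" if mean is None else repr(float(mean)),
            ])
    sidecar = {
        "name": model.name,
        "platform": model.platform,
        "transform": model.transform.to_dict(),
        "n_train": model.n_train,
        "seed": model.seed,
        "cpgs": list(model.coefficients),
    }
    with open(sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")


def read_clock_model(path):
    """Read a clock written by :func:`write_clock_model`.

    A coefficient CSV without the training_mean column loads with
    imputation disabled (``training_means=None``); a sidecar CpG list that
    disagrees with the CSV is a consistency error.
    """
    from .clock_training import ClockModel  # local import: clock_training imports us
    from .age_transforms import AgeTransform

    path = Path(path)
    df = pd.read_csv(path, dtype={"term": str}, keep_default_na=False)
    if "term" not in df.columns or "coefficient" not in df.columns:
        raise FormatError("coefficient CSV must have term and coefficient columns")
    has_means = "training_mean" in df.columns
    terms = df["term"].tolist()
    if INTERCEPT_TERM not in terms:
        raise FormatError(f"coefficient CSV has no {INTERCEPT_TERM!r} row")
    intercept = float(df.loc[df["term"] == INTERCEPT_TERM, "coefficient"].iloc[0])
    rest = df[df["term"] != INTERCEPT_TERM]
    coefficients = {t: float(c) for t, c in zip(rest["term"], rest["coefficient"])}
    training_means = None
    if has_means:
        training_means = {}
        for t, m in zip(rest["term"], rest["training_mean"]):
            if str(m).strip() in MISSING_TOKENS:
                training_means = None
                break
            training_means[t] = float(m)

    side = sidecar_path(path)
    name, platform = path.stem, "custom"
    transform = AgeTransform("identity")
    n_train = seed = None
    if side.exists():
        with open(side) as fh:
            meta = json.load(fh)
        name = meta.get("name", name)
        platform = meta.get("platform", platform)
        transform = AgeTransform.from_dict(meta.get("transform", {"kind": "identity"}))
        n_train = meta.get("n_train")
        seed = meta.get("seed")
        side_cpgs = meta.get("cpgs")
        if side_cpgs is not None and set(side_cpgs) != set(coefficients):
            extra = sorted(set(side_cpgs) - set(coefficients))
            missing = sorted(set(coefficients) - set(side_cpgs))
            raise ConsistencyError(
                f"sidecar/CSV CpG mismatch: sidecar-only {extra[:5]}, "
                f"csv-only {missing[:5]}"
            )
    return ClockModel(
        name=name, platform=platform, intercept=intercept,
        coefficients=coefficients, transform=transform,
        training_means=training_means, n_train=n_train, seed=seed,
    )
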