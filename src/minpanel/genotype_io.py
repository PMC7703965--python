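"""Reading, writing and call-completeness statistics for genotype tables.

The on-disk layout is the one used for fingerprinting spreadsheets: a
header row of marker IDs, a first column of sample IDs, and two-letter
genotype cells ("AA", "AG", ...) with a token for no-calls.  Genotypes are
unordered ("GA" and "AG" are the same call) and are canonicalized on read.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ParameterError, ValidationError
from .types import HET, HOM_X, HOM_Y, MISSING, GenotypeMatrix, MarkerInfo, SampleInfo

#: Tokens accepted as a no-call by default (the empty cell plus common aliases).
DEFAULT_MISSING_TOKENS: tuple[str, ...] = ("", "NA", "--", "NN")

_NUCLEOTIDES = frozenset("ACGT")


def _open_text(source: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", newline=""), True
    return source, False


def _pick_delimiter(source: str | Path | TextIO, first_line: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    if isinstance(source, (str, Path)) and str(source).endswith((".tsv", ".txt")):
        return "\t"
    return "\t" if "\t" in first_line else ","


def read_genotype_table(
    source: str | Path | TextIO,
    *,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    delimiter: str | None = None,
    markers: Sequence[MarkerInfo] | None = None,
    samples: Sequence[SampleInfo] | None = None,
) -> GenotypeMatrix:
    """Parse a CSV/TSV genotype table into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    source:
        Path or open text stream.  First row: marker IDs (the top-left cell
        is ignored).  Each further row: sample ID followed by genotype cells.
    missing_tokens:
        Cell values treated as a no-call.  Matching is case-insensitive.
    delimiter:
        ``","`` or ``"\\t"``; inferred from the filename / first line when
        omitted.
    markers:
        Optional marker metadata.  When given, each marker's allele pair is
        taken from it and any cell letter outside that pair is an error.
        When omitted, allele pairs are inferred from the observed letters
        (alphabetical orientation).
    samples:
        Optional sample metadata, matched by ``sample_id``; samples in the
        table but absent from the metadata get bare records.

    Raises
    ------
    FormatError
        Ragged rows or a cell that is neither a two-letter genotype nor a
        missing token.
    ValidationError
        Duplicate sample/marker IDs, or an allele letter outside the
        marker's declared pair (the offending cell is named).
    """
    stream, owned = _open_text(source)
    try:
        first_line = stream.readline()
        if not first_line.strip():
            raise EmptyInputError("genotype table is empty")
        delim = _pick_delimiter(source, first_line, delimiter)
        header = next(csv.reader([first_line], delimiter=delim))
        marker_ids = [h.strip() for h in header[1:]]
        if len(set(marker_ids)) != len(marker_ids):
            dups = sorted({m for m in marker_ids if marker_ids.count(m) > 1})
            raise ValidationError(f"duplicate marker IDs: {dups}")
        if not marker_ids:
            raise FormatError("header row contains no marker IDs")

        missing_set = {t.upper() for t in missing_tokens}
        sample_ids: list[str] = []
        # raw[i][j] = canonicalized two-letter string or None for missing
        raw: list[list[str | None]] = []
        for lineno, row in enumerate(csv.reader(stream, delimiter=delim), start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) != len(marker_ids) + 1:
                raise FormatError(
                    f"line {lineno}: expected {len(marker_ids) + 1} fields, got {len(row)}"
                )
            sid = row[0].strip()
            if sid in sample_ids:
                raise ValidationError(f"duplicate sample ID {sid!r}")
            sample_ids.append(sid)
            cells: list[str | None] = []
            for mid, cell in zip(marker_ids, row[1:]):
                cell = cell.strip().upper()
                if cell in missing_set:
                    cells.append(None)
                    continue
                if len(cell) != 2 or any(c not in _NUCLEOTIDES for c in cell):
                    raise FormatError(
                        f"sample {sid!r}, marker {mid!r}: cell {cell!r} is not a "
                        f"two-letter genotype or missing token"
                    )
                # unordered genotype: canonicalize to alphabetical order
                cells.append("".join(sorted(cell)))
            raw.append(cells)
    finally:
        if owned:
            stream.close()

    if not sample_ids:
        raise EmptyInputError("genotype table has no sample rows")

    marker_meta = _resolve_markers(marker_ids, raw, markers)
    sample_meta = _resolve_samples(sample_ids, samples)

    calls = np.full((len(sample_ids), len(marker_ids)), MISSING, dtype=np.int8)
    for j, info in enumerate(marker_meta):
        x, y = info.allele_x, info.allele_y
        hom_x = x + x
        het = "".join(sorted(x + y)) if y is not None else None
        hom_y = y + y if y is not None else None
        for i, cells in enumerate(raw):
            cell = cells[j]
            if cell is None:
                continue
            if cell == hom_x:
                calls[i, j] = HOM_X
            elif cell == het:
                calls[i, j] = HET
            elif cell == hom_y:
                calls[i, j] = HOM_Y
            else:
                raise ValidationError(
                    f"sample {sample_ids[i]!r}, marker {info.marker_id!r}: "
                    f"genotype {cell!r} uses alleles outside the marker's "
                    f"{x}/{y} pair"
                )
    return GenotypeMatrix(samples=sample_meta, markers=marker_meta, calls=calls)


def _resolve_markers(
    marker_ids: list[str],
    raw: list[list[str | None]],
    markers: Sequence[MarkerInfo] | None,
) -> list[MarkerInfo]:
    if markers is not None:
        by_id = {m.marker_id: m for m in markers}
        out = []
        for mid in marker_ids:
            if mid not in by_id:
                raise ValidationError(f"marker {mid!r} absent from marker metadata")
            out.append(by_id[mid])
        return out
    # infer allele pairs from the observed letters, alphabetical orientation
    out = []
    for j, mid in enumerate(marker_ids):
        letters: set[str] = set()
        for cells in raw:
            if cells[j] is not None:
                letters.update(cells[j])  # type: ignore[arg-type]
        if len(letters) > 2:
            raise ValidationError(
                f"marker {mid!r}: more than two alleles observed ({sorted(letters)})"
            )
        if not letters:
            out.append(MarkerInfo(marker_id=mid, allele_x="N", allele_y=None))
        else:
            pair = sorted(letters)
            out.append(
                MarkerInfo(
                    marker_id=mid,
                    allele_x=pair[0],
                    allele_y=pair[1] if len(pair) == 2 else None,
                )
            )
    return out


def _resolve_samples(
    sample_ids: list[str], samples: Sequence[SampleInfo] | None
) -> list[SampleInfo]:
    if samples is None:
        return [SampleInfo(sample_id=sid) for sid in sample_ids]
    by_id = {s.sample_id: s for s in samples}
    return [by_id.get(sid, SampleInfo(sample_id=sid)) for sid in sample_ids]


def write_genotype_table(
    matrix: GenotypeMatrix,
    dest: str | Path | TextIO,
    *,
    missing_token: str = "NA",
    delimiter: str = ",",
) -> None:
    """Write a matrix back to CSV/TSV in the layout `read_genotype_table` reads."""
    frame = matrix.to_frame(missing_token=missing_token)
    if isinstance(dest, (str, Path)):
        frame.to_csv(dest, sep=delimiter)
    else:
        frame.to_csv(dest, sep=delimiter)


def read_marker_info(source: str | Path | TextIO) -> list[MarkerInfo]:
    """Read marker metadata CSV: marker_id, chromosome, allele_x, allele_y[, primers]."""
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    required = {"marker_id", "allele_x", "allele_y"}
    if not required.issubset(df.columns):
        raise FormatError(f"marker metadata needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        primers = None
        if "primers" in df.columns and row["primers"]:
            parts = tuple(p.strip() for p in row["primers"].split(";"))
            if len(parts) == 3:
                primers = parts  # type: ignore[assignment]
        out.append(
            MarkerInfo(
                marker_id=row["marker_id"],
                chromosome=row.get("chromosome") or None,
                allele_x=row["allele_x"].upper(),
                allele_y=row["allele_y"].upper() or None,
                primer_sequences=primers,
            )
        )
    return out


def read_sample_info(source: str | Path | TextIO) -> list[SampleInfo]:
    """Read sample metadata CSV: sample_id[, variety_name, replicate_label, ploidy]."""
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError("sample metadata needs a sample_id column")
    out = []
    for _, row in df.iterrows():
        ploidy = row.get("ploidy", "")
        out.append(
            SampleInfo(
                sample_id=row["sample_id"],
                variety_name=row.get("variety_name") or None,
                replicate_label=row.get("replicate_label") or None,
                reported_ploidy=int(ploidy) if ploidy else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Fail-rate statistics and the minimum-calls retention filter
# ---------------------------------------------------------------------------


def marker_fail_rates(matrix: GenotypeMatrix) -> tuple[pd.DataFrame, float]:
    """Per-marker no-call counts and rates, plus the overall no-call fraction.

    Returns a DataFrame indexed by marker_id with columns ``n_missing`` and
    ``fail_rate`` (missing calls at the marker divided by sample count), and
    the overall fraction of missing cells in the whole table.
    """
    if matrix.n_samples == 0 or matrix.n_markers == 0:
        raise EmptyInputError("cannot compute fail rates of an empty matrix")
    missing = matrix.calls == MISSING
    per_marker = missing.sum(axis=0)
    df = pd.DataFrame(
        {
            "n_missing": per_marker,
            "fail_rate": per_marker / matrix.n_samples,
        },
        index=pd.Index(matrix.marker_ids, name="marker_id"),
    )
    overall = float(missing.sum()) / (matrix.n_samples * matrix.n_markers)
    return df, overall


def sample_call_counts(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample counts of called and failed markers."""
    if matrix.n_samples == 0 or matrix.n_markers == 0:
        raise EmptyInputError("cannot compute call counts of an empty matrix")
    called = (matrix.calls >= 0).sum(axis=1)
    return pd.DataFrame(
        {
            "n_called": called,
            "n_missing": matrix.n_markers - called,
        },
        index=pd.Index(matrix.sample_ids, name="sample_id"),
    )


def filter_by_min_calls(
    matrix: GenotypeMatrix, min_calls: int
) -> tuple[GenotypeMatrix, list[str]]:
    """Keep samples with at least ``min_calls`` non-missing calls.

    Returns the retained matrix (sample order preserved) and the list of
    removed sample IDs.  Screening out samples with too many failed assays
    is the standard guard against low-quality DNA before profile grouping.
    """
    if not (0 <= min_calls <= matrix.n_markers):
        raise ParameterError(
            f"min_calls must be in [0, {matrix.n_markers}], got {min_calls}"
        )
    called = (matrix.calls >= 0).sum(axis=1)
    keep = called >= min_calls
    retained = matrix.subset_samples(np.nonzero(keep)[0])
    removed = [sid for sid, k in zip(matrix.sample_ids, keep) if not k]
    return retained, removed


__all__ = [
    "DEFAULT_MISSING_TOKENS",
    "read_genotype_table",
    "write_genotype_table",
    "read_marker_info",
    "read_sample_info",
    "marker_fail_rates",
    "sample_call_counts",
    "filter_by_min_calls",
]
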