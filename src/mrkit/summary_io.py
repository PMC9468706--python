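"""Read, validate and write GWAS summary-statistics tables, and harmonize
exposure/outcome records onto a common effect allele.

A summary table is delimited text (tab or comma) with a header row. Column
names are mapped onto the canonical field names of
:class:`SummaryStatRecord` through a ``column_map`` (canonical name ->
source column name); identity mapping is assumed for missing entries.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

__all__ = [
    "SummaryStatRecord",
    "HarmonizedInstrument",
    "SummaryTableError",
    "read_summary_table",
    "write_summary_table",
    "harmonize",
    "COMPLEMENT",
    "CANONICAL_FIELDS",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order used by :func:`write_summary_table`
CANONICAL_FIELDS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "eaf",
    "pval",
    "n",
)

_REQUIRED_FIELDS = tuple(f for f in CANONICAL_FIELDS if f != "eaf")


class SummaryTableError(ValueError):
    """Raised for configuration problems (missing columns) or invalid rows."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the log odds ratio per copy of ``effect_allele``; ``eaf``
    is the effect-allele frequency and may be ``None`` when the source
    table does not provide it.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: Optional[float] = None

    def validation_errors(self) -> list[str]:
        problems = []
        if self.effect_allele not in COMPLEMENT:
            problems.append(f"effect_allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in COMPLEMENT:
            problems.append(f"other_allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            problems.append("effect_allele equals other_allele")
        if not (self.se > 0) or not math.isfinite(self.se):
            problems.append(f"se must be > 0, got {self.se!r}")
        if not math.isfinite(self.beta):
            problems.append(f"beta must be finite, got {self.beta!r}")
        if not (0 < self.pval <= 1):
            problems.append(f"pval must be in (0, 1], got {self.pval!r}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            problems.append(f"eaf must be in (0, 1), got {self.eaf!r}")
        if self.pos < 1:
            problems.append(f"pos must be >= 1, got {self.pos!r}")
        if self.n < 1:
            problems.append(f"n must be a positive integer, got {self.n!r}")
        return problems

    def validate(self) -> "SummaryStatRecord":
        problems = self.validation_errors()
        if problems:
            raise SummaryTableError(
                f"invalid record {self.snp_id!r}: " + "; ".join(problems)
            )
        return self

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP with exposure and outcome effects on the same effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float] = None
    eaf_out: Optional[float] = None
    palindromic: bool = False
    flipped: bool = False

    def __post_init__(self):
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(
                f"{self.snp_id}: standard errors must be positive "
                f"(se_exp={self.se_exp}, se_out={self.se_out})"
            )


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def _parse_float(raw: str, field_name: str):
    raw = raw.strip()
    if raw in ("", "NA", "NaN", "nan", "."):
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"unparseable {field_name}: {raw!r}") from None


def read_summary_table(path, column_map: Optional[dict] = None) -> list[SummaryStatRecord]:
    """Read a delimited summary-statistics table into validated records.

    Parameters
    ----------
    path : str or Path
        Tab- or comma-delimited text file with a header row.
    column_map : dict, optional
        Mapping of canonical field name -> column name in the file.
        Fields not mentioned default to their canonical name.

    Raises
    ------
    SummaryTableError
        If a required column is missing, or any row fails validation.
        All offending rows are reported together with 1-based line
        numbers; nothing is silently dropped.
    """
    column_map = dict(column_map or {})
    mapping = {f: column_map.get(f, f) for f in CANONICAL_FIELDS}

    with open(path, "r", newline="") as fh:
        sample = fh.read(8192)
        fh.seek(0)
        delim = _sniff_delimiter(sample.splitlines()[0] if sample else "")
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [
            f for f in _REQUIRED_FIELDS if mapping[f] not in header
        ]
        if missing:
            raise SummaryTableError(
                f"{path}: missing required column(s) "
                + ", ".join(f"{mapping[f]!r} (field {f})" for f in missing)
            )
        has_eaf = mapping["eaf"] in header

        records: list[SummaryStatRecord] = []
        errors: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                eaf = _parse_float(row[mapping["eaf"]], "eaf") if has_eaf else None
                rec = SummaryStatRecord(
                    snp_id=row[mapping["snp_id"]].strip(),
                    chrom=str(row[mapping["chrom"]]).strip(),
                    pos=int(row[mapping["pos"]]),
                    effect_allele=row[mapping["effect_allele"]].strip().upper(),
                    other_allele=row[mapping["other_allele"]].strip().upper(),
                    beta=_require(_parse_float(row[mapping["beta"]], "beta"), "beta"),
                    se=_require(_parse_float(row[mapping["se"]], "se"), "se"),
                    eaf=eaf,
                    pval=_require(_parse_float(row[mapping["pval"]], "pval"), "pval"),
                    n=int(float(row[mapping["n"]])),
                )
            except (ValueError, KeyError) as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            problems = rec.validation_errors()
            if problems:
                errors.append(
                    f"line {lineno} ({rec.snp_id}): " + "; ".join(problems)
                )
            else:
                records.append(rec)
    if errors:
        raise SummaryTableError(
            f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors)
        )
    return records


def _require(value, field_name: str):
    if value is None:
        raise ValueError(f"missing required value for {field_name}")
    return value


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return format(value, ".17g")
    return str(value)


def write_summary_table(records: Sequence[SummaryStatRecord], path) -> None:
    """Write records as a tab-delimited table in canonical column order.

    Floats are written with 17 significant digits so that read∘write is
    the identity at full double precision.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANONICAL_FIELDS)
        for rec in records:
            writer.writerow([_fmt(getattr(rec, f)) for f in CANONICAL_FIELDS])


# ---------------------------------------------------------------------------
# harmonization


def _align_by_labels(exp: SummaryStatRecord, out: SummaryStatRecord):
    """Match outcome alleles to the exposure pair by swap and/or strand
    complementation.  Returns (sign, complemented) or None when the pairs
    cannot be reconciled."""
    pairs = [
        ((out.effect_allele, out.other_allele), False),
        ((COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele]), True),
    ]
    target = (exp.effect_allele, exp.other_allele)
    for (ea, oa), complemented in pairs:
        if (ea, oa) == target:
            return 1, complemented
        if (oa, ea) == target:
            return -1, complemented
    return None


def harmonize(
    exposure: Iterable[SummaryStatRecord],
    outcome: Iterable[SummaryStatRecord],
    palindromic_policy: str = "infer_by_eaf",
    eaf_window: float = 0.08,
    audit: Optional[list] = None,
) -> list[HarmonizedInstrument]:
    """Align outcome effects to the exposure effect allele, SNP by SNP.

    SNPs absent from the outcome table are excluded. Non-palindromic
    alleles are aligned by label, trying a strand complement before
    declaring a mismatch; a swap flips the sign of the outcome beta.
    Palindromic SNPs (A/T, C/G) cannot be aligned from labels alone and
    are handled per ``palindromic_policy``:

    ``"drop"``
        always excluded.
    ``"infer_by_eaf"``
        kept when both effect-allele frequencies are outside
        ``[0.5 - eaf_window, 0.5 + eaf_window]``; opposite sides of 0.5
        imply opposite strands and the outcome beta is sign-flipped.
        Missing EAF on either side drops the SNP.

    Every exclusion is appended to ``audit`` (if given) as a
    ``(snp_id, reason)`` tuple. |beta_out| and se_out are never changed;
    only signs and allele labels are.
    """
    if palindromic_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindromic_policy {palindromic_policy!r}")
    if audit is None:
        audit = []

    out_by_id: dict[str, SummaryStatRecord] = {}
    for rec in outcome:
        out_by_id[rec.snp_id] = rec

    instruments: list[HarmonizedInstrument] = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            audit.append((exp.snp_id, "absent_from_outcome"))
            continue

        aligned = _align_by_labels(exp, out)
        if aligned is None:
            audit.append((exp.snp_id, "allele_mismatch"))
            continue
        sign, complemented = aligned
        eaf_out = out.eaf
        if sign < 0 and eaf_out is not None:
            eaf_out = 1.0 - eaf_out

        flipped = sign < 0 or complemented
        if exp.is_palindromic:
            if palindromic_policy == "drop":
                audit.append((exp.snp_id, "palindromic_dropped"))
                continue
            # strand is unresolvable from labels; decide from EAF sides
            if exp.eaf is None or eaf_out is None:
                audit.append((exp.snp_id, "palindromic_missing_eaf"))
                continue
            lo, hi = 0.5 - eaf_window, 0.5 + eaf_window
            if lo <= exp.eaf <= hi or lo <= eaf_out <= hi:
                audit.append((exp.snp_id, "palindromic_eaf_ambiguous"))
                continue
            if (exp.eaf < 0.5) != (eaf_out < 0.5):
                sign = -sign
                eaf_out = 1.0 - eaf_out
                flipped = True

        instruments.append(
            HarmonizedInstrument(
                snp_id=exp.snp_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=sign * out.beta,
                se_out=out.se,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
                palindromic=exp.is_palindromic,
                flipped=flipped,
            )
        )
    return instruments


def write_audit(audit: Sequence[tuple], path) -> None:
    """Write the harmonization audit as a two-column TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["snp_id", "reason"])
        writer.writerows(audit)
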