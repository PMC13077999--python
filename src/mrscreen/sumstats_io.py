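"""GWAS summary-statistics and LD-reference I/O and the shared data model.

Summary statistics arrive as delimited text with one row per variant
(GWAS-SSF-like column names by default; the mapping is explicit, never
guessed). LD arrives as a pre-computed pairwise correlation table — the
package never touches genotypes. Coordinates are 1-based and alleles are
reported on the forward strand of whatever build the input uses; positions
are opaque beyond distance windowing.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, fields

import pandas as pd
from scipy import stats

VALID_ALLELES = frozenset("ACGT")

#: Default column mapping, matching GWAS-SSF header names.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "rsid",
    "chromosome": "chromosome",
    "position": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "standard_error",
    "pvalue": "p_value",
    "eaf": "effect_allele_frequency",
    "n": "n",
}

MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se")

#: Relative tolerance on the z scale for the p-vs-beta/se consistency check.
#: Published GWAS round p-values, so disagreement below 10% only warns.
PZ_RELATIVE_TOL = 0.10


class SumstatsError(ValueError):
    """Hard error reading or validating a summary-statistics file."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One variant's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele``: log-odds for a
    binary trait, SD units for a continuous one.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chromosome: str = ""
    position: int = 0
    eaf: float | None = None
    n: float | None = None

    def invariant_violations(self) -> list[str]:
        """Reasons this record fails the hard data-model invariants."""
        problems = []
        if self.effect_allele not in VALID_ALLELES:
            problems.append("effect_allele_not_single_nucleotide")
        if self.other_allele not in VALID_ALLELES:
            problems.append("other_allele_not_single_nucleotide")
        if self.effect_allele == self.other_allele:
            problems.append("alleles_identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            problems.append("se_not_positive")
        if not (0 < self.pvalue <= 1):
            problems.append("pvalue_out_of_range")
        if self.eaf is not None and not (0 < self.eaf < 1):
            problems.append("eaf_out_of_range")
        if not math.isfinite(self.beta):
            problems.append("beta_not_finite")
        return problems

    def pz_consistent(self, rel_tol: float = PZ_RELATIVE_TOL) -> bool:
        """True when pvalue and |beta|/se agree within ``rel_tol`` on z."""
        z_obs = abs(self.beta) / self.se
        z_p = float(stats.norm.isf(self.pvalue / 2.0))
        if not math.isfinite(z_p):  # p too small to invert; compare p instead
            return True
        ref = max(z_obs, z_p, 1e-12)
        return abs(z_obs - z_p) / ref <= rel_tol

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass
class ReadReport:
    """Per-file accounting of dropped and flagged records."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    drop_reasons: Counter = field(default_factory=Counter)
    n_pz_warnings: int = 0
    n_duplicates: int = 0


class SummaryStatSet:
    """One trait's GWAS: an ordered collection of records keyed by variant id."""

    def __init__(self, trait_id: str, trait_type: str = "continuous",
                 records: list[SummaryStatRecord] | None = None):
        if trait_type not in ("continuous", "binary"):
            raise SumstatsError(f"unknown trait_type {trait_type!r}")
        self.trait_id = trait_id
        self.trait_type = trait_type
        self._records: dict[str, SummaryStatRecord] = {}
        self.read_report: ReadReport | None = None
        for rec in records or []:
            self.add(rec)

    def add(self, record: SummaryStatRecord) -> None:
        if record.variant_id in self._records:
            raise SumstatsError(
                f"duplicate variant_id {record.variant_id!r} in {self.trait_id!r}")
        self._records[record.variant_id] = record

    def get(self, variant_id: str) -> SummaryStatRecord | None:
        return self._records.get(variant_id)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    @property
    def records(self) -> list[SummaryStatRecord]:
        return list(self._records.values())

    @property
    def variant_ids(self) -> list[str]:
        return list(self._records)

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in fields(SummaryStatRecord)]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self])


class LDReference:
    """Signed pairwise LD correlations within a genomic window.

    Pairs absent from the table are r = 0 (different chromosome, beyond the
    window, or simply uncatalogued). The table is symmetric and r(a,a) = 1.
    ``signed`` records the input dialect: an unsigned r² table supports
    clumping but not proxy allele alignment.
    """

    def __init__(self, window_bp: int = 10_000_000, signed: bool = True):
        self.window_bp = int(window_bp)
        self.signed = signed
        self._entries: dict[tuple[str, str], float] = {}
        self.positions: dict[str, tuple[str, int]] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r: float) -> None:
        if abs(r) > 1:
            raise SumstatsError(f"|r| > 1 for pair ({a}, {b}): {r}")
        if a == b:
            return
        self._entries[self._key(a, b)] = float(r)

    def r(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._entries.get(self._key(a, b), 0.0)

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2

    def partners(self, a: str) -> dict[str, float]:
        """All catalogued partners of ``a`` with their signed r."""
        out = {}
        for (x, y), r in self._entries.items():
            if x == a:
                out[y] = r
            elif y == a:
                out[x] = r
        return out

    def __len__(self) -> int:
        return len(self._entries)


def _coerce_float(value, allow_missing: bool = False) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        if allow_missing:
            return None
        return math.nan
    try:
        return float(value)
    except (TypeError, ValueError):
        return None if allow_missing else math.nan


def read_sumstats(path, column_map: dict[str, str] | None = None,
                  trait_type: str = "continuous", trait_id: str | None = None,
                  sep: str = "\t") -> SummaryStatSet:
    """Read a delimited summary-statistics file into a validated set.

    Records violating the data-model invariants are dropped and counted in
    the returned set's ``read_report``; p-vs-z inconsistencies only warn.
    gzip input is handled transparently by pandas.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, sep=sep, dtype={cmap.get("chromosome", ""): str})
    except pd.errors.EmptyDataError:
        raise SumstatsError(f"empty summary-statistics file: {path}") from None
    if df.empty:
        raise SumstatsError(f"summary-statistics file has no data rows: {path}")
    for field_name in MANDATORY_FIELDS:
        col = cmap.get(field_name)
        if col is None or col not in df.columns:
            raise SumstatsError(
                f"mandatory column {col!r} (field {field_name!r}) missing from {path}")

    have = {f: cmap[f] for f in cmap if cmap[f] in df.columns}
    report = ReadReport(n_rows=len(df))
    out = SummaryStatSet(trait_id or str(path), trait_type=trait_type)
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        get = lambda f: row.get(have[f]) if f in have else None
        pval = _coerce_float(get("pvalue"), allow_missing=True)
        rec = SummaryStatRecord(
            variant_id=str(get("variant_id")),
            effect_allele=str(get("effect_allele")).upper(),
            other_allele=str(get("other_allele")).upper(),
            beta=_coerce_float(get("beta")),
            se=_coerce_float(get("se")),
            pvalue=pval if pval is not None else math.nan,
            chromosome=str(get("chromosome")) if get("chromosome") is not None else "",
            position=int(get("position")) if get("position") is not None
            and not pd.isna(get("position")) else 0,
            eaf=_coerce_float(get("eaf"), allow_missing=True),
            n=_coerce_float(get("n"), allow_missing=True),
        )
        problems = rec.invariant_violations()
        if problems:
            report.n_dropped += 1
            report.drop_reasons.update(problems)
            continue
        if rec.variant_id in out:
            report.n_dropped += 1
            report.n_duplicates += 1
            report.drop_reasons.update(["duplicate_variant_id"])
            continue
        if not rec.pz_consistent():
            report.n_pz_warnings += 1
        out.add(rec)
        report.n_kept += 1
    out.read_report = report
    return out


def write_sumstats(sumstats: SummaryStatSet, path, sep: str = "\t") -> None:
    """Write a set back out with GWAS-SSF column names (lossless round-trip)."""
    df = sumstats.to_frame().rename(columns=DEFAULT_COLUMN_MAP)
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_ld_table(path, dialect: str = "r", window_bp: int = 10_000_000,
                  sep: str = "\t") -> LDReference:
    """Read a pairwise LD table (columns: id_a, id_b, r or r²).

    ``dialect='r'`` means signed correlations; ``dialect='r2'`` means
    unsigned squared correlations (stored as sqrt(r²); proxy allele
    alignment is then refused downstream).
    """
    if dialect not in ("r", "r2"):
        raise SumstatsError(f"unknown LD dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise SumstatsError(f"empty LD table: {path}") from None
    if df.shape[1] < 3:
        raise SumstatsError("LD table needs at least 3 columns (id_a, id_b, r)")
    ld = LDReference(window_bp=window_bp, signed=(dialect == "r"))
    a_col, b_col, r_col = df.columns[:3]
    for a, b, val in zip(df[a_col], df[b_col], df[r_col]):
        val = float(val)
        if dialect == "r2":
            if not (0 <= val <= 1):
                raise SumstatsError(f"r² out of [0,1] for pair ({a}, {b}): {val}")
            val = math.sqrt(val)
        ld.add(str(a), str(b), val)
    return ld


def write_ld_table(ld: LDReference, path, sep: str = "\t") -> None:
    rows = [{"id_a": a, "id_b": b, "r": r} for (a, b), r in sorted(ld._entries.items())]
    pd.DataFrame(rows, columns=["id_a", "id_b", "r"]).to_csv(
        path, sep=sep, index=False, float_format="%.12g")


def write_results(battery_table, path, sep: str = "\t") -> None:
    """Write a collection of MRBattery results as a flat TSV.

    Round-tripping the file reproduces all numeric fields to 12 significant
    digits. An empty collection yields a header-only file.
    """
    from mrscreen.screen import battery_frame  # local import: avoid cycle

    df = battery_frame(list(battery_table))
    try:
        df.to_csv(path, sep=sep, index=False, float_format="%.12g")
    except OSError as exc:
        raise SumstatsError(f"cannot write results to {path}: {exc}") from exc


def read_results(path, sep: str = "\t") -> pd.DataFrame:
    """Read back a battery TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep=sep)
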