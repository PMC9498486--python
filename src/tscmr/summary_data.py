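"""Reading, validation and allele harmonization of GWAS summary statistics.

Two-sample Mendelian randomization combines per-variant association
estimates from separate GWAS.  Before any arithmetic, the studies must
agree on which allele the effect size refers to: effect alleles are
aligned to a *base* study, swapped-allele records are sign-flipped, and
strand-ambiguous (palindromic A/T, G/C) variants whose allele frequency
cannot resolve the strand are discarded.

The module is positionless: records are keyed by ``snp_id`` only, and
inputs are assumed to be pre-clumped (LD pruning requires an external
reference panel and is out of scope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from scipy import stats

from ._errors import ConfigError, InputError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Standard field names and common aliases found in GWAS summary files.
DEFAULT_ALIASES: dict[str, str] = {
    "snp": "snp_id",
    "rsid": "snp_id",
    "variant": "snp_id",
    "markername": "snp_id",
    "snp_id": "snp_id",
    "effect_allele": "effect_allele",
    "ea": "effect_allele",
    "a1": "effect_allele",
    "other_allele": "other_allele",
    "oa": "other_allele",
    "a2": "other_allele",
    "non_effect_allele": "other_allele",
    "eaf": "eaf",
    "effect_allele_freq": "eaf",
    "freq": "eaf",
    "maf": "eaf",
    "beta": "beta",
    "b": "beta",
    "effect": "beta",
    "se": "se",
    "standard_error": "se",
    "stderr": "se",
    "pval": "pval",
    "p": "pval",
    "p_value": "pval",
    "pvalue": "pval",
    "n": "n",
    "samplesize": "n",
    "sample_size": "n",
}

MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se")


@dataclass(frozen=True)
class SummaryAssociation:
    """One variant's association with one phenotype.

    ``beta`` is the per-allele effect of ``effect_allele`` (phenotype
    units for quantitative traits, log odds for binary traits).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pval: float | None = None
    n: int | None = None

    def validate(self) -> str | None:
        """Return a reason string if the record violates an invariant, else None."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "invalid allele"
        if self.effect_allele == self.other_allele:
            return "identical alleles"
        if not (self.se > 0):
            return "nonpositive SE"
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            return "EAF outside [0,1]"
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            return "p-value outside (0,1]"
        if self.n is not None and self.n <= 0:
            return "nonpositive sample size"
        return None

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "SummaryAssociation":
        """The same association expressed for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def p_value(self) -> float:
        """Reported p-value, or a two-sided normal p from beta/se."""
        if self.pval is not None:
            return self.pval
        return float(2.0 * stats.norm.sf(abs(self.beta) / self.se))


class PhenotypeStats(NamedTuple):
    """Per-phenotype slot of a harmonized record."""

    beta: float
    se: float
    eaf: float | None


# Harmonization outcomes.
KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_INCOMPATIBLE = "dropped_incompatible"


@dataclass(frozen=True)
class HarmonizedRecord:
    """Exposure/outcome (or any base/other) pair aligned to one effect allele.

    For dropped records the ``other`` slot holds the source values as
    read (for audit); downstream code must use only records whose action
    is ``kept`` or ``flipped``.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    base: PhenotypeStats
    other: PhenotypeStats
    action: str

    @property
    def usable(self) -> bool:
        return self.action in (KEPT, FLIPPED)


def _resolve_columns(
    columns: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map file column names to standard fields; error on missing mandatory fields."""
    mapping: dict[str, str] = {}
    explicit = dict(column_map or {})
    for col in columns:
        if col in explicit:
            mapping[col] = explicit[col]
        elif col.lower() in DEFAULT_ALIASES:
            mapping[col] = DEFAULT_ALIASES[col.lower()]
    assigned = set(mapping.values())
    missing = [f for f in MANDATORY_FIELDS if f not in assigned]
    if missing:
        raise ConfigError(
            f"summary-statistic file is missing mandatory column(s): {', '.join(missing)} "
            f"(available columns: {', '.join(columns)}; supply a column_map)"
        )
    return mapping


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SummaryAssociation]:
    """Read GWAS summary statistics from a delimited text file.

    Parameters
    ----------
    path
        TSV or CSV file with a header row.  The delimiter is chosen by
        extension (``.csv`` for comma, otherwise tab).
    column_map
        Optional mapping from file column names to standard fields
        (``snp_id``, ``effect_allele``, ``other_allele``, ``eaf``,
        ``beta``, ``se``, ``pval``, ``n``).  Columns matching common
        aliases are recognized automatically.

    Rows that violate record invariants (nonpositive SE, bad alleles,
    out-of-range EAF/p) are skipped and logged; row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str)
    mapping = _resolve_columns(list(frame.columns), column_map)
    frame = frame.rename(columns=mapping)[list(dict.fromkeys(mapping.values()))]

    records: list[SummaryAssociation] = []
    n_skipped = 0
    for i, row in enumerate(frame.itertuples(index=False)):
        d = row._asdict()
        try:
            rec = SummaryAssociation(
                snp_id=str(d["snp_id"]),
                effect_allele=str(d["effect_allele"]).strip().upper(),
                other_allele=str(d["other_allele"]).strip().upper(),
                beta=float(d["beta"]),
                se=float(d["se"]),
                eaf=float(d["eaf"]) if d.get("eaf") not in (None, "") and pd.notna(d.get("eaf")) else None,
                pval=float(d["pval"]) if d.get("pval") not in (None, "") and pd.notna(d.get("pval")) else None,
                n=int(float(d["n"])) if d.get("n") not in (None, "") and pd.notna(d.get("n")) else None,
            )
        except (TypeError, ValueError):
            logger.warning("%s row %d skipped: unparseable numeric field", path.name, i)
            n_skipped += 1
            continue
        reason = rec.validate()
        if reason is not None:
            logger.warning("%s row %d (%s) skipped: %s", path.name, i, rec.snp_id, reason)
            n_skipped += 1
            continue
        records.append(rec)
    if not records:
        raise InputError(f"{path}: zero parseable rows ({n_skipped} skipped)")
    return records


def _near_half(eaf: float | None, window: float) -> bool:
    return eaf is None or abs(eaf - 0.5) < window


def harmonize(
    base: Iterable[SummaryAssociation],
    other: Iterable[SummaryAssociation],
    palindrome_eaf_window: float = 0.08,
) -> list[HarmonizedRecord]:
    """Align ``other`` to the effect alleles of ``base``.

    Allele pairs matching after swap are sign-flipped (beta negated, EAF
    complemented); pairs matching only after strand complement are
    relabelled; palindromic variants are resolved by allele frequency
    when both EAFs are farther than ``palindrome_eaf_window`` from 0.5,
    and dropped otherwise.  Irreconcilable allele sets are dropped as
    incompatible.  Only SNPs present in both inputs are returned, in
    base order.
    """
    if not (0.0 <= palindrome_eaf_window < 0.5):
        raise ConfigError("palindrome_eaf_window must lie in [0, 0.5)")
    base_by_id = _index_by_snp(base, "base")
    other_by_id = _index_by_snp(other, "other")

    out: list[HarmonizedRecord] = []
    for snp_id, b in base_by_id.items():
        o = other_by_id.get(snp_id)
        if o is None:
            continue
        out.append(_harmonize_pair(b, o, palindrome_eaf_window))
    return out


def _index_by_snp(
    records: Iterable[SummaryAssociation], which: str
) -> dict[str, SummaryAssociation]:
    index: dict[str, SummaryAssociation] = {}
    for rec in records:
        if rec.snp_id in index:
            raise InputError(f"duplicated snp_id {rec.snp_id!r} in {which} records")
        index[rec.snp_id] = rec
    return index


def _harmonize_pair(
    b: SummaryAssociation, o: SummaryAssociation, window: float
) -> HarmonizedRecord:
    def result(o_aligned: SummaryAssociation, action: str) -> HarmonizedRecord:
        return HarmonizedRecord(
            snp_id=b.snp_id,
            effect_allele=b.effect_allele,
            other_allele=b.other_allele,
            base=PhenotypeStats(b.beta, b.se, b.eaf),
            other=PhenotypeStats(o_aligned.beta, o_aligned.se, o_aligned.eaf),
            action=action,
        )

    b_ea, b_oa = b.effect_allele, b.other_allele
    if b.is_palindromic:
        # Strand cannot be inferred from allele letters; fall back on EAF.
        if {o.effect_allele, o.other_allele} != {b_ea, b_oa}:
            return result(o, DROPPED_INCOMPATIBLE)
        if _near_half(b.eaf, window) or _near_half(o.eaf, window):
            return result(o, DROPPED_PALINDROMIC)
        o_aligned = o if o.effect_allele == b_ea else o.flipped()
        same_side = (b.eaf < 0.5) == (o_aligned.eaf < 0.5)
        if same_side:
            return result(o_aligned, KEPT if o.effect_allele == b_ea else FLIPPED)
        # Frequencies disagree: the studies report opposite strands, so the
        # letter-matched allele is actually the complementary (other) allele.
        o_aligned = o_aligned.flipped()
        return result(o_aligned, KEPT if o.effect_allele != b_ea else FLIPPED)

    for transform in (lambda r: r, _complemented):
        ot = transform(o)
        if (ot.effect_allele, ot.other_allele) == (b_ea, b_oa):
            return result(ot, KEPT)
        if (ot.other_allele, ot.effect_allele) == (b_ea, b_oa):
            return result(ot.flipped(), FLIPPED)
    return result(o, DROPPED_INCOMPATIBLE)


def _complemented(rec: SummaryAssociation) -> SummaryAssociation:
    """Relabel a record onto the opposite strand (no sign or EAF change)."""
    return replace(
        rec,
        effect_allele=COMPLEMENT[rec.effect_allele],
        other_allele=COMPLEMENT[rec.other_allele],
    )


def filter_instruments(
    assocs: Iterable[SummaryAssociation],
    p_threshold: float = 5e-8,
) -> list[SummaryAssociation]:
    """Keep associations with p strictly below ``p_threshold``.

    The reported p-value is used when present, otherwise a two-sided
    normal p is computed from beta/se.  Order is preserved.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ConfigError("p_threshold must lie in (0, 1]")
    kept = [a for a in assocs if a.p_value() < p_threshold]
    if not kept:
        logger.warning("no instruments pass p < %g", p_threshold)
    return kept


def harmonized_to_frame(records: Iterable[HarmonizedRecord]) -> pd.DataFrame:
    """Tabulate harmonized records (one row per SNP, audit column included)."""
    rows = []
    for r in records:
        rows.append(
            {
                "snp_id": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "beta_base": r.base.beta,
                "se_base": r.base.se,
                "eaf_base": r.base.eaf,
                "beta_other": r.other.beta,
                "se_other": r.other.se,
                "eaf_other": r.other.eaf,
                "harmonization_action": r.action,
            }
        )
    return pd.DataFrame(rows)


def write_harmonized(records: Iterable[HarmonizedRecord], path: str | Path) -> None:
    """Write the harmonized table as TSV with a harmonization_action column."""
    harmonized_to_frame(records).to_csv(path, sep="\t", index=False)
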