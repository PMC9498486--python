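"""Two-step cis-MR adjustment of variant-outcome associations.

A crude variant-outcome association decomposes into the path through
the exposure of interest and any path through a correlated or
pleiotropic confounder phenotype.  The biasing path equals the product
of the variant-confounder association (``b_gc``, from a GWAS of the
confounder) and the confounder-outcome causal effect (``b_co``, from an
MR of the confounder on the outcome).  Subtracting that product yields
an adjusted variant-outcome association usable in any two-sample MR
analysis:

    b_adj = b_go - b_gc * b_co

Uncertainty is propagated assuming the three estimates come from
independent samples.  The exact variance of a product of two
independent normals gives

    se_pe^2 = se_go^2 + b_gc^2 se_co^2 + b_co^2 se_gc^2 + se_gc^2 se_co^2

with the last (cross) term dropped under the first-order delta method.
A seeded parametric bootstrap provides a cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import InputError

DEFAULT_N_BOOT = 10_000


@dataclass(frozen=True)
class PathwaySpec:
    """One biasing pathway: variant -> confounder -> outcome.

    b_gc : variant-confounder association (confounder units per allele)
    b_co : confounder -> outcome causal estimate (outcome units per
           confounder unit), typically from an MR of the confounder
    """

    b_gc: float
    se_gc: float
    b_co: float
    se_co: float
    label: str = ""

    def __post_init__(self) -> None:
        # Zero SEs are tolerated as degenerate (point-mass) estimates so
        # that known-exact pathway components can be expressed.
        if self.se_gc < 0 or self.se_co < 0:
            raise InputError("pathway SEs must be nonnegative")

    @property
    def product(self) -> float:
        """The subtracted path effect b_gc * b_co."""
        return self.b_gc * self.b_co

    def product_variance(self, first_order: bool = False) -> float:
        """Variance of the product of the two independent estimates."""
        v = self.b_gc**2 * self.se_co**2 + self.b_co**2 * self.se_gc**2
        if not first_order:
            v += self.se_gc**2 * self.se_co**2
        return v


@dataclass(frozen=True)
class AdjustmentResult:
    """Adjusted variant-outcome association with propagated uncertainty."""

    b_adj: float
    se_pe: float
    subtracted: tuple[float, ...]
    se_bs: float | None = None
    n_boot: int = 0
    seed: int | None = None
    snp_id: str | None = None


class PathwayIndependenceWarning(UserWarning):
    """Sequential adjustment assumes mutually independent biasing pathways."""


def adjust_association(
    b_go: float,
    se_go: float,
    pathway: PathwaySpec,
    first_order: bool = False,
) -> AdjustmentResult:
    """Subtract one biasing pathway from a variant-outcome association.

    Parameters
    ----------
    b_go, se_go
        Crude variant-outcome association and its standard error.
    pathway
        The biasing pathway to remove.
    first_order
        Drop the ``se_gc^2 * se_co^2`` cross term from the propagated
        variance (first-order delta method) instead of using the exact
        product-of-independent-normals variance.
    """
    if not se_go > 0:
        raise InputError("se_go must be positive")
    var = se_go**2 + pathway.product_variance(first_order=first_order)
    return AdjustmentResult(
        b_adj=b_go - pathway.product,
        se_pe=math.sqrt(var),
        subtracted=(pathway.product,),
    )


def sequential_adjust(
    b_go: float,
    se_go: float,
    pathways: Sequence[PathwaySpec],
    first_order: bool = False,
) -> AdjustmentResult:
    """Subtract several biasing pathways, accumulating variance additively.

    Validity requires the pathways to be mutually independent: if one
    confounder causes another, their paths share a segment and the shared
    contribution is subtracted twice (overadjustment).  A
    ``PathwayIndependenceWarning`` is emitted as a reminder.
    """
    if not se_go > 0:
        raise InputError("se_go must be positive")
    if len(pathways) == 0:
        raise InputError("at least one pathway is required")
    if len(pathways) > 1:
        warnings.warn(
            "sequential adjustment is only valid when the biasing pathways are "
            "mutually independent; shared path segments are subtracted twice",
            PathwayIndependenceWarning,
            stacklevel=2,
        )
    subtracted = tuple(p.product for p in pathways)
    var = se_go**2 + sum(p.product_variance(first_order=first_order) for p in pathways)
    return AdjustmentResult(
        b_adj=b_go - sum(subtracted),
        se_pe=math.sqrt(var),
        subtracted=subtracted,
    )


def bootstrap_se(
    b_go: float,
    se_go: float,
    pathway: PathwaySpec | Sequence[PathwaySpec],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    first_order: bool = False,
) -> AdjustmentResult:
    """Parametric-bootstrap standard error for the adjusted association.

    Draws ``b_go*``, ``b_gc*``, ``b_co*`` independently from normal
    distributions centred on the estimates with their standard errors as
    SDs, and reports the sample SD of ``b_go* - sum_k b_gc,k* b_co,k*``.
    Deterministic for a fixed seed; the point estimate and propagated SE
    are identical to :func:`adjust_association` / :func:`sequential_adjust`.
    """
    if n_boot < 100:
        raise InputError("n_boot must be at least 100")
    pathways = [pathway] if isinstance(pathway, PathwaySpec) else list(pathway)
    base = sequential_adjust(b_go, se_go, pathways, first_order=first_order) \
        if len(pathways) > 1 else adjust_association(b_go, se_go, pathways[0], first_order)
    rng = np.random.default_rng(seed)
    draws = rng.normal(b_go, se_go, n_boot)
    for p in pathways:
        gc = rng.normal(p.b_gc, p.se_gc, n_boot)
        co = rng.normal(p.b_co, p.se_co, n_boot)
        draws = draws - gc * co
    return AdjustmentResult(
        b_adj=base.b_adj,
        se_pe=base.se_pe,
        subtracted=base.subtracted,
        se_bs=float(np.std(draws, ddof=1)),
        n_boot=n_boot,
        seed=seed,
    )


def adjust_table(
    outcome: pd.DataFrame,
    confounder: pd.DataFrame,
    b_co: float,
    se_co: float,
    n_boot: int | None = None,
    seed: int = 0,
    first_order: bool = False,
    label: str = "",
) -> pd.DataFrame:
    """Vectorize :func:`adjust_association` over an instrument table.

    Parameters
    ----------
    outcome
        Per-SNP variant-outcome associations with columns ``snp_id``,
        ``beta``, ``se`` (already harmonized to a common effect allele).
    confounder
        Per-SNP variant-confounder associations, same columns and
        allele orientation.
    b_co, se_co
        Single confounder-outcome causal estimate applied to every SNP.
    n_boot
        If given, additionally compute seeded bootstrap SEs.

    Instruments missing from the confounder table are excluded with a
    warning (imputing a zero confounder association would silently
    masquerade as "no bias").  Output rows follow input order.
    """
    required = {"snp_id", "beta", "se"}
    for name, df in (("outcome", outcome), ("confounder", confounder)):
        if not required.issubset(df.columns):
            raise InputError(f"{name} table must have columns {sorted(required)}")
    conf = confounder.set_index("snp_id")
    if conf.index.has_duplicates:
        raise InputError("duplicated snp_id in confounder table")
    missing = [s for s in outcome["snp_id"] if s not in conf.index]
    if missing:
        warnings.warn(
            f"{len(missing)} instrument(s) missing from confounder table, "
            f"excluded: {', '.join(map(str, missing))}",
            UserWarning,
            stacklevel=2,
        )
    rows = []
    for _, row in outcome[~outcome["snp_id"].isin(missing)].iterrows():
        c = conf.loc[row["snp_id"]]
        spec = PathwaySpec(
            b_gc=float(c["beta"]), se_gc=float(c["se"]),
            b_co=b_co, se_co=se_co, label=label,
        )
        if n_boot is None:
            res = adjust_association(row["beta"], row["se"], spec, first_order)
            se_bs = None
        else:
            res = bootstrap_se(row["beta"], row["se"], spec, n_boot, seed, first_order)
            se_bs = res.se_bs
        rows.append(
            {
                "snp_id": row["snp_id"],
                "beta_adj": res.b_adj,
                "se_pe": res.se_pe,
                "se_bs": se_bs,
                "subtracted_path": res.subtracted[0],
            }
        )
    return pd.DataFrame(rows, columns=["snp_id", "beta_adj", "se_pe", "se_bs", "subtracted_path"])
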