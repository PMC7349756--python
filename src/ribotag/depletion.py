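"""The depletion-efficiency statistic.

For each IP library the per-chromosome change in percent of uniquely
mapping reads (IP minus matched input) is regressed on the input percent,
separately for on-target and off-target chromosomes.  Off-target
chromosomes lose reads in proportion to their initial abundance, so the
regression is linear with a negative slope; the *depletion efficiency* is
the negative of that slope.  If every off-target read is removed, each
chromosome's change equals minus its initial percent (a chromosome at 5%
of the input loses all 5 points), the slope is -1 and the efficiency is 1
— the theoretical maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneTable, SampleSheet, pair_samples
from .composition import chrom_proportions, delta_table

__all__ = [
    "DepletionFit",
    "fit_depletion",
    "depletion_report",
    "classify_chromosome_direction",
]


@dataclass
class DepletionFit:
    """Ordinary least squares fit of delta percent on initial percent."""

    target_class: str
    species: str
    n_chromosomes: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    #: negative slope; populated for off-target fits only
    depletion_efficiency: float | None
    include_mito: bool
    through_origin: bool

    def as_dict(self) -> dict:
        return asdict(self)


def _ols_through_origin(x: np.ndarray, y: np.ndarray):
    """Slope, R² (uncentred) and slope t-test p for a no-intercept fit."""
    sxx = float(np.dot(x, x))
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    rss = float(np.dot(resid, resid))
    tss = float(np.dot(y, y))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    df = len(x) - 1
    if rss <= 0:
        p = 0.0
    else:
        se = np.sqrt(rss / df / sxx)
        t = slope / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return slope, r2, p


def fit_depletion(
    deltas: pd.DataFrame,
    target_class: str = "off",
    include_mito: bool | None = None,
    through_origin: bool = False,
) -> DepletionFit:
    """Fit the delta-vs-initial regression over one target class.

    ``deltas`` is a table from :func:`ribotag.composition.delta_table`.
    ``include_mito`` defaults to True for the off-target class and False
    for the on-target class: the on-target mitochondrial chromosome is not
    recovered by tagged cytosolic ribosomes and sits off the on-target
    trend, while off-target chromosomes (MT included) deplete together.

    Requires at least 3 chromosomes and non-degenerate initial percents.
    The p-value is the two-sided t-test of zero slope (n - 2 degrees of
    freedom; n - 1 through the origin).
    """
    if target_class not in ("on", "off"):
        raise ValueError("target_class must be 'on' or 'off'")
    if include_mito is None:
        include_mito = target_class == "off"
    sub = deltas[deltas["target_class"] == target_class]
    if not include_mito:
        sub = sub[~sub["is_mito"].astype(bool)]
    if len(sub) < 3:
        raise ValueError(
            f"need at least 3 chromosomes in class {target_class!r}, got {len(sub)}"
        )
    x = sub["initial_percent"].to_numpy(dtype=float)
    y = sub["delta_percent"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("initial percents have zero variance; slope undefined")
    species = sorted(sub["species"].unique())
    species_label = species[0] if len(species) == 1 else "+".join(species)
    if through_origin:
        slope, r2, p = _ols_through_origin(x, y)
        intercept = 0.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, p = float(res.slope), float(res.intercept), float(res.pvalue)
        r2 = float(res.rvalue) ** 2
    return DepletionFit(
        target_class=target_class,
        species=species_label,
        n_chromosomes=len(sub),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        p_value=p,
        depletion_efficiency=(-slope) if target_class == "off" else None,
        include_mito=include_mito,
        through_origin=through_origin,
    )


def depletion_report(
    counts,
    gene_table: GeneTable,
    sheet: SampleSheet,
    mode: str = "chromosome_level",
    include_mito_on: bool = False,
    include_mito_off: bool = True,
    through_origin: bool = False,
    fit_on_target: bool = True,
) -> pd.DataFrame:
    """One regression row per (IP, target class) over all paired samples.

    Reproduces the published table layout: sample identity, IP/input
    pairing, species whose chromosomes entered the fit, slope, R², p and
    (for off-target rows) the depletion efficiency.  An ``rna_yield_ng``
    column in the sheet is passed through.
    """
    rows = []
    for ip_sample, input_sample in pair_samples(sheet):
        on_species = sheet.df.loc[ip_sample, "on_target_species"]
        in_props = chrom_proportions(counts, gene_table, input_sample, mode=mode)
        ip_props = chrom_proportions(counts, gene_table, ip_sample, mode=mode)
        deltas = delta_table(in_props, ip_props, gene_table, on_species)
        classes = [("off", include_mito_off)]
        if fit_on_target:
            classes.insert(0, ("on", include_mito_on))
        for target_class, inc_mito in classes:
            fit = fit_depletion(
                deltas,
                target_class=target_class,
                include_mito=inc_mito,
                through_origin=through_origin,
            )
            row = {
                "ip_sample": ip_sample,
                "input_sample": input_sample,
                "antibody": sheet.df.loc[ip_sample, "antibody"],
                "on_target_species": on_species,
                **fit.as_dict(),
            }
            if "rna_yield_ng" in sheet.df.columns:
                row["rna_yield_ng"] = sheet.df.loc[ip_sample, "rna_yield_ng"]
            rows.append(row)
    return pd.DataFrame(rows)


def classify_chromosome_direction(deltas: pd.DataFrame) -> pd.Series:
    """Label each chromosome enriched (delta > 0), depleted (< 0) or unchanged."""
    d = deltas["delta_percent"].to_numpy()
    labels = np.where(d > 0, "enriched", np.where(d < 0, "depleted", "unchanged"))
    return pd.Series(labels, index=deltas["chromosome"].to_numpy(), name="direction")
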