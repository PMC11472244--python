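"""Per-zone orchestration and the cross-zone comparative synthesis.

`run_zone` chains the stages for one hybrid zone: admixture filters ->
hybrid index -> allele-sharing permutation test -> geographic clines (one
per MHC class plus genome-wide) -> genomic clines.  Stage failures are
captured per stage with the reason recorded (e.g. a strongly bimodal
genome-wide ancestry distribution skips the genomic cline; a winning
no-cline null excludes the transect from cline comparison) and the run
continues.

`run_comparative` pools zone-level results across species pairs and fits
the PGLS families (MHC-class model, with/without divergence time and the
class x time interaction, compared by LRT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .allele_sharing import SharingTestResult, near_far_test
from .comparative import (
    PairCorrelationMatrix,
    PGLSFit,
    aggregate_transects,
    lrt,
    pair_correlation_matrix,
    pgls_fit,
)
from .data_model import (
    BinaryGenotypeMatrix,
    IndividualRecord,
    MhcClass,
    ZoneCategory,
    ZoneConfig,
    filter_nonadmixed,
)
from .genomic_clines import GenomicClineFit, fit_genomic_cline, orient_alpha
from .geo_clines import (
    GeographicClineFit,
    center_shift,
    fit_geographic_cline,
    hedges_g_from_intervals,
    select_cline_model,
)
from .hybrid_index import estimate_hybrid_indices, reference_frequencies_from_matrix

__all__ = ["ZoneResult", "run_zone", "run_comparative"]

_CLINE_MODELS = ("none", "fixed", "free", "no_cline")


@dataclass
class ZoneResult:
    config: ZoneConfig
    sharing: dict[MhcClass, SharingTestResult] = field(default_factory=dict)
    hybrid_index: dict[MhcClass, pd.DataFrame] = field(default_factory=dict)
    geo_fit_gw: GeographicClineFit | None = None
    geo_fits_mhc: dict[MhcClass, GeographicClineFit] = field(default_factory=dict)
    width_g: dict[MhcClass, tuple[float, tuple[float, float]]] = field(default_factory=dict)
    center_shift_km: dict[MhcClass, float] = field(default_factory=dict)
    genomic: dict[MhcClass, GenomicClineFit] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    seed: int | None = None


def _population_table(values: pd.Series, positions: pd.Series, localities: pd.Series) -> pd.DataFrame:
    df = pd.DataFrame({"v": values, "x": positions, "loc": localities}).dropna()
    grouped = df.groupby("loc").agg(
        x=("x", "mean"), mean=("v", "mean"), n=("v", "size"), sd=("v", "std")
    )
    grouped["sd"] = grouped["sd"].fillna(0.0)
    return grouped.reset_index(drop=True)


def _fit_and_select(pop_table: pd.DataFrame) -> GeographicClineFit:
    fits = []
    for model in _CLINE_MODELS:
        try:
            fits.append(fit_geographic_cline(pop_table, model, compute_intervals=False))
        except ValueError:
            continue
    best = select_cline_model(fits)
    if best.model != "no_cline":
        best = fit_geographic_cline(pop_table, best.model, compute_intervals=True)
    return best


def run_zone(
    cfg: ZoneConfig,
    matrices: dict[MhcClass, BinaryGenotypeMatrix],
    individuals: list[IndividualRecord],
    less_diverse_side: str | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> ZoneResult:
    """Run the three introgression tests for one hybrid zone.

    ``less_diverse_side`` ('increasing_x' / 'decreasing_x') orients the
    cline-center shift; omit it to skip that contrast.  The hybrid index is
    oriented so h measures ancestry from the first species of
    ``cfg.species_pair``.
    """
    result = ZoneResult(config=cfg, seed=seed)
    sp1, sp2 = cfg.species_pair
    by_id = {r.individual_id: r for r in individuals}

    # --- allele sharing on filtered nonadmixed individuals
    try:
        pure = filter_nonadmixed(individuals, cfg)
    except ValueError as e:
        pure = []
        result.skipped["filter"] = str(e)
    for mhc_class, matrix in matrices.items():
        if pure:
            usable = [r for r in pure if r.individual_id in set(matrix.individual_ids)]
            try:
                result.sharing[mhc_class] = near_far_test(
                    matrix, usable, n_perm=n_perm, seed=seed
                )
            except ValueError as e:
                result.skipped[f"sharing[{mhc_class.value}]"] = str(e)

    # --- hybrid index per class, references from 'far' individuals
    for mhc_class, matrix in matrices.items():
        in_matrix = set(matrix.individual_ids)
        ref1 = [
            r.individual_id
            for r in individuals
            if r.species == sp1 and r.zone_category == ZoneCategory.FAR and r.individual_id in in_matrix
        ]
        ref2 = [
            r.individual_id
            for r in individuals
            if r.species == sp2 and r.zone_category == ZoneCategory.FAR and r.individual_id in in_matrix
        ]
        if not ref1 or not ref2:
            result.skipped[f"hybrid_index[{mhc_class.value}]"] = "no 'far' reference individuals for one species"
            continue
        refs = reference_frequencies_from_matrix(matrix, ref1, ref2)
        keep_cols = [matrix.allele_ids.index(a) for a in refs.allele_ids]
        h = estimate_hybrid_indices(matrix.presence[:, keep_cols], refs)
        result.hybrid_index[mhc_class] = pd.DataFrame(
            {"individual_id": matrix.individual_ids, "h": h, "n_markers": len(refs.allele_ids)}
        )

    # --- geographic clines: genome-wide from Q, MHC from HI
    meta = pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in individuals],
            "q": [r.q_score for r in individuals],
            "x": [r.transect_position_km for r in individuals],
            "loc": [r.locality_id for r in individuals],
        }
    ).set_index("individual_id")
    have_positions = meta["x"].notna().any()
    if have_positions:
        gw_table = _population_table(meta["q"], meta["x"], meta["loc"])
        try:
            result.geo_fit_gw = _fit_and_select(gw_table)
        except ValueError as e:
            result.skipped["geo_cline[genome_wide]"] = str(e)
        for mhc_class, hi_df in result.hybrid_index.items():
            hi = hi_df.set_index("individual_id")["h"].reindex(meta.index)
            mhc_table = _population_table(hi, meta["x"], meta["loc"])
            try:
                fit = _fit_and_select(mhc_table)
            except ValueError as e:
                result.skipped[f"geo_cline[{mhc_class.value}]"] = str(e)
                continue
            result.geo_fits_mhc[mhc_class] = fit
            gw = result.geo_fit_gw
            if fit.excluded_no_cline or gw is None or gw.excluded_no_cline:
                result.skipped[f"cline_contrast[{mhc_class.value}]"] = "no-cline model selected"
                continue
            if "width" in fit.support_intervals and "width" in gw.support_intervals:
                result.width_g[mhc_class] = hedges_g_from_intervals(
                    fit.width, fit.support_intervals["width"],
                    gw.width, gw.support_intervals["width"], seed=seed,
                )
            if less_diverse_side is not None:
                result.center_shift_km[mhc_class] = center_shift(fit, gw, less_diverse_side)
    else:
        result.skipped["geo_clines"] = "no transect positions supplied"

    # --- genomic clines from (q, hi) of admixed individuals
    for mhc_class, hi_df in result.hybrid_index.items():
        merged = hi_df.set_index("individual_id").join(meta[["q"]], how="inner").dropna(subset=["q"])
        pairs = merged[["q", "h"]].to_numpy()
        try:
            fit = fit_genomic_cline(pairs, admixture_window=(cfg.admixed_threshold, 1 - cfg.admixed_threshold))
        except ValueError as e:
            result.skipped[f"genomic_cline[{mhc_class.value}]"] = str(e)
            continue
        result.genomic[mhc_class] = orient_alpha(fit, cfg, species1=sp1)
    return result


def _ci_to_variance(ci: tuple[float, float]) -> float:
    sd = (ci[1] - ci[0]) / (2 * 1.959963984540054)
    return sd * sd


def run_comparative(
    zone_results: dict[tuple[str, str], "ZoneResult | list[ZoneResult]"],
    tree,
    divergence_times: dict[tuple[str, str], float] | None = None,
) -> dict[str, Any]:
    """PGLS synthesis of zone-level results across species pairs.

    ``zone_results`` maps species pairs to one or more ZoneResults
    (replicate transects of a pair are averaged).  Returns a report dict
    with, per response family (ses, alpha, beta), the class-only fit and —
    when divergence times are supplied — the time and interaction models
    with the LRT p-value for the interaction.
    """
    if len(zone_results) < 2:
        return {"skipped": "comparative synthesis needs >= 2 hybrid zones"}
    pairs = list(zone_results.keys())
    corr = pair_correlation_matrix(tree, pairs)

    rows = []
    for pair, results in zone_results.items():
        if isinstance(results, ZoneResult):
            results = [results]
        for res in results:
            for mhc_class, sharing in res.sharing.items():
                if sharing.ses is not None:
                    rows.append(
                        {"pair": pair, "mhc_class": mhc_class.value, "family": "ses",
                         "response": sharing.ses, "variance": 1.0}
                    )
            for mhc_class, fit in res.genomic.items():
                for family, value, name in (
                    ("alpha", fit.alpha, "alpha"),
                    ("beta", fit.beta, "beta"),
                ):
                    var = (
                        _ci_to_variance(fit.support_intervals[name])
                        if name in fit.support_intervals
                        else np.nan
                    )
                    rows.append(
                        {"pair": pair, "mhc_class": mhc_class.value, "family": family,
                         "response": value, "variance": var}
                    )
            for mhc_class, (g, ci) in res.width_g.items():
                rows.append(
                    {"pair": pair, "mhc_class": mhc_class.value, "family": "width_g",
                     "response": g, "variance": _ci_to_variance(ci)}
                )
    table = pd.DataFrame(rows)
    report: dict[str, Any] = {"data": table, "pairs": pairs}
    for family, sub in table.groupby("family"):
        agg = aggregate_transects(sub)
        if len(agg) < 3:
            report[family] = {"skipped": "too few observations"}
            continue
        weights = None if family in ("ses",) else "inverse_variance"
        if weights and agg["variance"].isna().any():
            weights = None
        entry: dict[str, Any] = {
            "class_model": pgls_fit(agg, corr, ["class"], weights=weights)
        }
        if divergence_times is not None:
            agg = agg.assign(time=[divergence_times[p] for p in agg["pair"]])
            n_classes = agg["mhc_class"].nunique()
            full_terms = ["class", "time", "class:time"] if n_classes > 1 else None
            with_time = pgls_fit(agg, corr, ["class", "time"], weights=weights)
            entry["time_model"] = with_time
            if full_terms:
                full = pgls_fit(agg, corr, full_terms, weights=weights)
                entry["interaction_model"] = full
                entry["interaction_lrt_p"] = lrt(full, with_time)
        report[family] = entry
    return report
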