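"""End-to-end orchestration: landmarks or tables in, summary tables out.

``run_pipeline`` accepts either a directory of per-specimen ``.pp`` landmark
files (with an optional ``specimens.csv`` metadata sidecar carrying taxon and
broken flags) or a flat measurements table, then:

1. measures element lengths (2 dp, mm) and assembles bilateral records,
2. computes signed percent asymmetry and direction classes,
3. applies the 3-SD length screen per taxon x element x side (and, on
   request, the post hoc PA screen),
4. runs the frequency chi-square and paired t-test per taxon x element and
   marks significance at the raw and Bonferroni-corrected thresholds,
5. writes measurement, asymmetry, exclusion, summary and rank-magnitude
   tables, plus a machine-parseable log of every exclusion decision.

The rank-magnitude data mirror the standard display for directional
asymmetry: per sample, the |PA| of left-larger and of right-larger
individuals, each sorted descending, with the percentage of individuals in
each class (left% + right% <= 100; the remainder are 0%-asymmetry
individuals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

from .asymmetry import (
    LEFT_LARGER,
    RIGHT_LARGER,
    AsymmetryRecord,
    TaxonTraitSample,
    build_samples,
    flag_asymmetry_outliers,
    flag_length_outliers,
)
from .inference import TaxonSummary, format_p, summarize_taxon
from .landmarks import LandmarkNamingConfig, PickedPointsError, map_landmarks, parse_picked_points
from .morphometry import ElementMeasurement, measure_specimen

__all__ = [
    "RankMagnitudePlotData",
    "PipelineResult",
    "run_pipeline",
    "rank_magnitude_data",
    "load_measurements_csv",
    "measurements_from_directory",
    "measurements_frame",
    "asymmetry_frame",
    "summary_frame",
    "plot_rank_magnitude",
]

MEASUREMENT_COLUMNS = [
    "taxon",
    "specimen_id",
    "element",
    "left_length",
    "right_length",
    "excluded",
    "exclusion_reason",
]


@dataclass(frozen=True)
class RankMagnitudePlotData:
    """Sorted |PA| magnitudes by direction class, with class percentages of N."""

    taxon: str
    element: str
    left_magnitudes: tuple[float, ...]   # |PA| of left-larger individuals, descending
    right_magnitudes: tuple[float, ...]  # |PA| of right-larger individuals, descending
    pct_left: float
    pct_right: float
    pct_symmetric: float


def rank_magnitude_data(sample: TaxonTraitSample) -> RankMagnitudePlotData:
    """Rank-magnitude display data for one sample (order-independent)."""
    active = [r for r in sample.active_records if r.percent_asymmetry is not None]
    if not active:
        raise ValueError(f"{sample.taxon}/{sample.element}: no records with asymmetry values")
    n = len(active)
    left = sorted((abs(r.percent_asymmetry) for r in active if r.direction == LEFT_LARGER), reverse=True)
    right = sorted((abs(r.percent_asymmetry) for r in active if r.direction == RIGHT_LARGER), reverse=True)
    return RankMagnitudePlotData(
        taxon=sample.taxon,
        element=sample.element,
        left_magnitudes=tuple(left),
        right_magnitudes=tuple(right),
        pct_left=100.0 * len(left) / n,
        pct_right=100.0 * len(right) / n,
        pct_symmetric=100.0 * (n - len(left) - len(right)) / n,
    )


# ---------------------------------------------------------------------------
# input loading

def load_measurements_csv(path: Union[str, Path]) -> list[ElementMeasurement]:
    """Read a flat left/right length table (columns as written by this module)."""
    df = pd.read_csv(path)
    missing = {"taxon", "specimen_id", "element", "left_length", "right_length"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        excluded = bool(getattr(row, "excluded", False))
        reason = getattr(row, "exclusion_reason", "none")
        if isinstance(reason, float) and math.isnan(reason):
            reason = "none"
        out.append(
            ElementMeasurement(
                taxon=str(row.taxon),
                specimen_id=str(row.specimen_id),
                element=str(row.element),
                left_length=None if pd.isna(row.left_length) else float(row.left_length),
                right_length=None if pd.isna(row.right_length) else float(row.right_length),
                excluded=excluded,
                exclusion_reason=reason if excluded else "none",
            )
        )
    return out


def measurements_from_directory(
    input_dir: Union[str, Path],
    naming: LandmarkNamingConfig | None = None,
) -> list[ElementMeasurement]:
    """Measure every ``*.pp`` file in a directory (specimen id = file stem).

    An optional ``specimens.csv`` sidecar (columns ``specimen_id``, ``taxon``,
    ``broken``) supplies what landmark files cannot: taxon assignment and
    broken-element flags.  Unreadable files are collected and reported together
    in a single error.
    """
    input_dir = Path(input_dir)
    naming = naming or LandmarkNamingConfig.default()
    pp_files = sorted(input_dir.glob("*.pp"))
    if not pp_files:
        raise FileNotFoundError(f"no .pp landmark files found in {input_dir}")

    meta: dict[str, dict] = {}
    sidecar = input_dir / "specimens.csv"
    if sidecar.exists():
        mdf = pd.read_csv(sidecar)
        for row in mdf.itertuples(index=False):
            meta[str(row.specimen_id)] = {
                "taxon": str(getattr(row, "taxon", "unknown")),
                "broken": bool(getattr(row, "broken", False)),
            }

    measurements: list[ElementMeasurement] = []
    failures: list[str] = []
    for path in pp_files:
        specimen_id = path.stem
        info = meta.get(specimen_id, {"taxon": "unknown", "broken": False})
        try:
            landmarks = parse_picked_points(path)
            lset = map_landmarks(
                landmarks, naming, specimen_id=specimen_id,
                taxon=info["taxon"], broken=info["broken"],
            )
        except (PickedPointsError, ValueError) as exc:
            failures.append(f"{path.name}: {exc}")
            continue
        measurements.extend(measure_specimen(lset))
    if failures:
        raise PickedPointsError("unreadable landmark files:\n  " + "\n  ".join(failures))
    return measurements


# ---------------------------------------------------------------------------
# tabular views

def measurements_frame(measurements: Iterable[ElementMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "taxon": m.taxon,
            "specimen_id": m.specimen_id,
            "element": m.element,
            "left_length": m.left_length,
            "right_length": m.right_length,
            "excluded": m.excluded,
            "exclusion_reason": m.exclusion_reason,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def asymmetry_frame(samples: Iterable[TaxonTraitSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for r in s.records:
            rows.append(
                {
                    "taxon": r.taxon,
                    "specimen_id": r.specimen_id,
                    "element": r.element,
                    "left_length": r.left_length,
                    "right_length": r.right_length,
                    "percent_asymmetry": r.percent_asymmetry,
                    "direction": r.direction,
                    "excluded": r.excluded,
                    "exclusion_reason": r.exclusion_reason,
                }
            )
    return pd.DataFrame(rows)


def summary_frame(summaries: Sequence[TaxonSummary]) -> pd.DataFrame:
    """One row per taxon x element, mirroring the standard report layout.

    Bold/italic significance marking is rendered as flag columns
    (``*_significant_raw``, ``*_significant_corrected``) plus bias direction.
    """
    rows = []
    for s in summaries:
        rows.append(
            {
                "taxon": s.taxon,
                "element": s.element,
                "N": s.n,
                "n_left_larger": s.n_left_larger,
                "n_right_larger": s.n_right_larger,
                "n_symmetric": s.n_symmetric,
                "chi2": round(s.frequency.chi2, 2),
                "chi2_p": s.frequency.p,
                "chi2_p_report": format_p(s.frequency.p),
                "mean_pa": round(s.magnitude.mean_pa, 2),
                "sd_pa": round(s.magnitude.sd_pa, 2),
                "t": round(s.magnitude.t, 2) if not math.isnan(s.magnitude.t) else float("nan"),
                "t_df": s.magnitude.df,
                "t_p": s.magnitude.p,
                "t_p_report": format_p(s.magnitude.p),
                "freq_significant_raw": s.freq_significant_raw,
                "freq_significant_corrected": s.freq_significant_corrected,
                "freq_bias": s.freq_bias,
                "mag_significant_raw": s.mag_significant_raw,
                "mag_significant_corrected": s.mag_significant_corrected,
                "mag_bias": s.mag_bias,
                "alpha": s.alpha,
                "bonferroni_alpha": round(s.bonferroni, 3),
            }
        )
    return pd.DataFrame(rows)


def _plot_data_frame(plots: Sequence[RankMagnitudePlotData]) -> pd.DataFrame:
    rows = []
    for p in plots:
        for side, mags in (("left", p.left_magnitudes), ("right", p.right_magnitudes)):
            for rank, mag in enumerate(mags, 1):
                rows.append(
                    {
                        "taxon": p.taxon,
                        "element": p.element,
                        "side": side,
                        "rank": rank,
                        "abs_percent_asymmetry": mag,
                        "pct_left": round(p.pct_left, 1),
                        "pct_right": round(p.pct_right, 1),
                        "pct_symmetric": round(p.pct_symmetric, 1),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class PipelineResult:
    samples: dict[tuple[str, str], TaxonTraitSample]
    summaries: list[TaxonSummary]
    plot_data: list[RankMagnitudePlotData]
    measurements: pd.DataFrame
    asymmetry: pd.DataFrame
    summary: pd.DataFrame
    exclusions: pd.DataFrame
    exclusion_log: list[str] = field(default_factory=list)


def run_pipeline(
    source: Union[str, Path, Sequence[ElementMeasurement]],
    naming: LandmarkNamingConfig | None = None,
    out_dir: Union[str, Path, None] = None,
    posthoc_asym_outliers: bool = False,
    paired_on: str = "lengths",
    family_alpha: float = 0.05,
    n_tests: int = 9,
    unexclude: Sequence[tuple[str, str]] = (),
) -> PipelineResult:
    """Run the full analysis and optionally write its artifact tables.

    ``source`` is a directory of ``.pp`` files, a measurements CSV path, or an
    in-memory measurement list.  ``unexclude`` lists ``(specimen_id, element)``
    pairs whose outlier flags a human has overridden after checking the
    digitization.  Deterministic given its inputs.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.is_dir():
            measurements = measurements_from_directory(path, naming)
        else:
            measurements = load_measurements_csv(path)
    else:
        measurements = list(source)
    if not measurements:
        raise ValueError("no measurements to analyze")

    records = [AsymmetryRecord.from_measurement(m) for m in measurements]
    samples = build_samples(records)

    log: list[str] = []
    for r in records:
        if r.excluded:
            log.append(f"EXCLUDE\t{r.taxon}\t{r.specimen_id}\t{r.element}\t{r.exclusion_reason}")

    filtered: dict[tuple[str, str], TaxonTraitSample] = {}
    overrides = set(unexclude)
    for key, sample in samples.items():
        before = {(r.specimen_id, r.element) for r in sample.records if r.excluded}
        sample = flag_length_outliers(sample)
        if posthoc_asym_outliers:
            sample = flag_asymmetry_outliers(sample)
        new_records = []
        for r in sample.records:
            if (
                r.excluded
                and r.exclusion_reason in ("outlier_length", "outlier_asymmetry")
                and (r.specimen_id, r.element) in overrides
            ):
                log.append(f"OVERRIDE\t{r.taxon}\t{r.specimen_id}\t{r.element}\t{r.exclusion_reason}")
                r = replace(r, excluded=False, exclusion_reason="none")
            elif r.excluded and (r.specimen_id, r.element) not in before:
                log.append(f"EXCLUDE\t{r.taxon}\t{r.specimen_id}\t{r.element}\t{r.exclusion_reason}")
            new_records.append(r)
        filtered[key] = TaxonTraitSample(taxon=sample.taxon, element=sample.element, records=new_records)

    order = sorted(filtered)
    summaries = [
        summarize_taxon(filtered[k], family_alpha=family_alpha, n_tests=n_tests, paired_on=paired_on)
        for k in order
    ]
    plots = [rank_magnitude_data(filtered[k]) for k in order]

    asym_df = asymmetry_frame([filtered[k] for k in order])
    excl_df = asym_df[asym_df["excluded"]][
        ["taxon", "specimen_id", "element", "exclusion_reason"]
    ].reset_index(drop=True)

    result = PipelineResult(
        samples=filtered,
        summaries=summaries,
        plot_data=plots,
        measurements=measurements_frame(measurements),
        asymmetry=asym_df,
        summary=summary_frame(summaries),
        exclusions=excl_df,
        exclusion_log=log,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.measurements.to_csv(out / "measurements.csv", index=False)
        result.asymmetry.to_csv(out / "asymmetry.csv", index=False)
        result.exclusions.to_csv(out / "exclusions.csv", index=False)
        result.summary.to_csv(out / "summary.csv", index=False)
        _plot_data_frame(plots).to_csv(out / "rank_magnitude.csv", index=False)
        (out / "exclusion_log.tsv").write_text("\n".join(log) + ("\n" if log else ""))
    return result


def plot_rank_magnitude(data: RankMagnitudePlotData, ax=None):
    """Thin renderer: bar chart of sorted |PA|, left-larger reflected leftward."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    nl = len(data.left_magnitudes)
    # left-larger individuals plotted left of the divider, largest outermost
    ax.bar(range(-nl, 0), data.left_magnitudes[::-1], color="tab:blue", label=f"left-larger ({data.pct_left:.0f}%)")
    ax.bar(
        range(1, len(data.right_magnitudes) + 1),
        data.right_magnitudes,
        color="tab:orange",
        label=f"right-larger ({data.pct_right:.0f}%)",
    )
    ax.axvline(0.5 - (nl > 0) * 0.0, color="k", lw=0.8)
    ax.set_xlabel("individual (ranked by |percent asymmetry|)")
    ax.set_ylabel("|percent asymmetry|")
    ax.set_title(f"{data.taxon} — {data.element}")
    ax.legend(frameon=False)
    return ax
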