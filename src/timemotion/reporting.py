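"""End-to-end analysis pipeline and report rendering.

Runs the estimators, resampling and agreement machinery over a validated
event log and renders the study-style outputs: a task-category time-budget
table (counts, hours, percent of total observation time with cluster
bootstrap CIs), a who×how breakdown of the three interactive categories
split drug-/non-drug-related, the composite "obtaining and documenting the
drug list" process proportion with its minutes-per-hour equivalent,
interruption and multitasking statistics, and Monte Carlo group contrasts.

Slice definitions are data, not code: the defaults below encode the
published row/cell definitions and can be overridden through
:class:`AnalysisConfig`.  Rendering is deterministic — identical inputs,
settings and seed produce byte-identical report files (percentages and
minutes are displayed rounded half-up to one decimal, agreement scores to
two; machine-readable CSV output keeps full precision).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .events import ALL, ObservationDataset, Selector
from .estimators import (
    EstimatorError,
    ProportionEstimate,
    fraction_tasks_interrupted,
    interruption_rate,
    interruption_reason_breakdown,
    minutes_per_hour,
    multitask_fraction,
    patients_per_session,
    proportion_of_time,
    time_on,
)
from .intervals import union
from .resampling import (
    InterruptionRateStatistic,
    SessionMeanStatistic,
    TimeProportionStatistic,
    bootstrap_ci,
    derive_seed,
    monte_carlo_group_test,
)
from .estimators import slice_interval_sets

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "category_table_rows",
    "who_how_table_cells",
    "composite_drug_list_selectors",
    "time_on_any",
    "proportion_of_time_any",
    "summarize_drug_list_process",
    "run_analysis",
    "render_report",
    "load_analysis_config",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (display rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Published slice definitions
# ---------------------------------------------------------------------------

_NON_DRUG_SUBS = frozenset(
    {"non-drug-related", "professional", "non-professional", "none"}
)

DRUG_RELATED = Selector.make(subcategory="drug-related")
NON_DRUG_RELATED = Selector(subcategory_in=_NON_DRUG_SUBS)


def category_table_rows() -> list[tuple[str, str, Selector]]:
    """(block, row label, selector) for the category time-budget table."""
    mk = Selector.make
    ndr = "non-drug-related"
    return [
        ("Non-drug-related", "Examination", mk(what="Examination/Treatment")),
        (
            "Non-drug-related",
            "Professional communication",
            mk(what="Professional communication", subcategory=ndr),
        ),
        (
            "Non-drug-related",
            "Gather information",
            mk(what="Gather information", subcategory=ndr),
        ),
        ("Non-drug-related", "Documentation", mk(what="Documentation", subcategory=ndr)),
        ("Non-drug-related", "Unknown", mk(what="Unknown")),
        (
            "Non-drug-related",
            "Social (both professional and non-professional)",
            mk(what="Social"),
        ),
        ("Non-drug-related", "Hygiene", mk(what="Hygiene")),
        ("Non-drug-related", "Movement", mk(what="Movement")),
        ("Non-drug-related", "Outside ED", mk(what="Outside ED")),
        (
            "Drug-related",
            "Professional communication",
            mk(what="Professional communication", subcategory="drug-related"),
        ),
        (
            "Drug-related",
            "Gather information",
            mk(what="Gather information", subcategory="drug-related"),
        ),
        (
            "Drug-related",
            "Documentation",
            mk(what="Documentation", subcategory="drug-related"),
        ),
    ]


_WHO_HOW_LAYOUT: list[tuple[str, Optional[str], Sequence[str] | None]] = [
    # (what, who, how labels)
    ("Professional communication", "Patient", ("Direct",)),
    ("Professional communication", "Next of kin", ("Direct",)),
    ("Professional communication", "Another physician", ("Direct", "Telephone")),
    ("Professional communication", "Nurse", ("Direct", "Telephone")),
    ("Professional communication", "Pharmacist", ("Direct",)),
    ("Professional communication", "Other hospital", ("Telephone",)),
    ("Professional communication", "Unknown", ("Direct", "Telephone")),
    ("Professional communication", "Others", ("Direct", "Telephone")),
    ("Professional communication", "General Practitioner", ("Telephone",)),
    ("Gather information", "Patient", ("Direct",)),
    ("Gather information", "Next of kin", ("Direct",)),
    ("Gather information", "Another physician", ("Direct",)),
    ("Gather information", "Nurse", ("Direct",)),
    ("Gather information", None, ("On paper",)),
    ("Gather information", None, ("On computer",)),
    ("Gather information", None, ("On smartphone",)),
    ("Gather information", None, ("With Prescription Intermediary",)),
    ("Documentation", None, ("On paper",)),
    ("Documentation", None, ("On computer",)),
    ("Documentation", None, ("With dictaphone",)),
    ("Documentation", None, ("With Prescription Intermediary",)),
]


def who_how_table_cells() -> list[tuple[str, str, Selector]]:
    """(subcategory block, cell label, selector) for the who×how table."""
    cells = []
    for sub in ("drug-related", "non-drug-related"):
        for what, who, how in _WHO_HOW_LAYOUT:
            label = f"{what} / {who or '-'} / {'+'.join(how)}"
            cells.append(
                (
                    sub,
                    label,
                    Selector.make(what=what, subcategory=sub, who=who, how=how),
                )
            )
    return cells


def composite_drug_list_selectors() -> list[Selector]:
    """Cells of the composite drug-list process (obtain + document).

    Drug-related gathering of information from the patient or next of kin,
    on paper, on computer or via the Prescription Intermediary, plus
    drug-related documentation on paper, computer or dictaphone.
    """
    mk = Selector.make
    gi = "Gather information"
    doc = "Documentation"
    dr = "drug-related"
    return [
        mk(what=gi, subcategory=dr, who="Patient", how="Direct"),
        mk(what=gi, subcategory=dr, who="Next of kin", how="Direct"),
        mk(what=gi, subcategory=dr, how="On paper"),
        mk(what=gi, subcategory=dr, how="On computer"),
        mk(what=gi, subcategory=dr, how="With Prescription Intermediary"),
        mk(what=doc, subcategory=dr, how="On paper"),
        mk(what=doc, subcategory=dr, how="On computer"),
        mk(what=doc, subcategory=dr, how="With dictaphone"),
    ]


# ---------------------------------------------------------------------------
# Multi-selector (union) slices
# ---------------------------------------------------------------------------


def time_on_any(dataset: ObservationDataset, selectors: Sequence[Selector]) -> int:
    """Seconds covered by the union of several selector slices."""
    total = 0
    per_session = [slice_interval_sets(dataset, s) for s in selectors]
    for sid in dataset.session_map():
        total += union(*[sets[sid] for sets in per_session]).total_length
    return total


def proportion_of_time_any(
    dataset: ObservationDataset, selectors: Sequence[Selector]
) -> ProportionEstimate:
    den = dataset.total_observation_seconds
    if den <= 0:
        raise EstimatorError("total observation time is zero")
    return ProportionEstimate(time_on_any(dataset, selectors), den)


@dataclass(frozen=True)
class UnionProportionStatistic:
    """Bootstrap statistic for a union-of-cells slice over total time."""

    selectors: tuple[Selector, ...]

    def __call__(self, dataset: ObservationDataset) -> float:
        return proportion_of_time_any(dataset, list(self.selectors)).proportion

    def cluster_components(self, cluster_datasets):
        import numpy as np

        return np.asarray(
            [
                (
                    time_on_any(sub, list(self.selectors)),
                    sub.total_observation_seconds,
                )
                for sub in cluster_datasets
            ],
            dtype=float,
        )

    def combine_sums(self, sums):
        import numpy as np

        sums = np.atleast_2d(sums)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(sums[:, 1] > 0, sums[:, 0] / sums[:, 1], np.nan)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Pipeline settings; slice definitions default to the published tables."""

    bootstrap_n_replicates: int = 10_000
    bootstrap_level: float = 0.95
    bootstrap_cluster: str = "physician"
    n_permutations: int = 9_999
    seed: int = 0
    group_tests: tuple[str, ...] = ("affiliation", "experience")
    composite: Optional[list[Selector]] = None

    def composite_selectors(self) -> list[Selector]:
        return self.composite if self.composite is not None else composite_drug_list_selectors()


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Load pipeline settings from YAML (keys: bootstrap.*, test.*, seed)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    boot = doc.get("bootstrap", {})
    test = doc.get("test", {})
    return AnalysisConfig(
        bootstrap_n_replicates=int(boot.get("n_replicates", 10_000)),
        bootstrap_level=float(boot.get("level", 0.95)),
        bootstrap_cluster=str(boot.get("cluster", "physician")),
        n_permutations=int(test.get("n_permutations", 9_999)),
        seed=int(doc.get("seed", 0)),
        group_tests=tuple(doc.get("group_tests", ("affiliation", "experience"))),
    )


def summarize_drug_list_process(
    dataset: ObservationDataset, config: Optional[AnalysisConfig] = None
) -> ProportionEstimate:
    """Proportion of total time on the composite drug-list process.

    The numerator is the union of the configured composite cells (so a
    second covered by two cells counts once); ``minutes_per_hour`` of the
    returned estimate gives the study-style minutes-per-hour figure.
    """
    config = config or AnalysisConfig()
    selectors = config.composite_selectors()
    if not selectors:
        raise EstimatorError("composite slice is empty")
    return proportion_of_time_any(dataset, selectors)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class ReportBundle:
    category_table: pd.DataFrame
    who_how_table: pd.DataFrame
    composite: dict
    interruptions: dict
    multitask: dict
    patients: dict
    group_tests: dict
    provenance: dict


def _n_tasks(dataset: ObservationDataset, selector: Selector) -> int:
    smap = dataset.session_map()
    return sum(
        1
        for r in dataset.records
        if r.session_id in smap and selector.matches(r, smap[r.session_id])
    )


def _slice_row(dataset, label, selector, config, seed_token):
    seconds = time_on(dataset, selector)
    row = {
        "slice": label,
        "n_tasks": _n_tasks(dataset, selector),
        "task_hours": seconds / 3600.0,
        # identical float path to ProportionEstimate.as_percent
        "percent": ProportionEstimate(
            seconds, dataset.total_observation_seconds
        ).as_percent,
        "ci_low": float("nan"),
        "ci_high": float("nan"),
    }
    if seconds > 0:
        boot = bootstrap_ci(
            dataset,
            TimeProportionStatistic(selector),
            level=config.bootstrap_level,
            n_replicates=config.bootstrap_n_replicates,
            seed=derive_seed(config.seed, "table", seed_token),
            cluster=config.bootstrap_cluster,
        )
        row["ci_low"] = 100.0 * boot.ci_low
        row["ci_high"] = 100.0 * boot.ci_high
    return row


def run_analysis(
    dataset: ObservationDataset, config: Optional[AnalysisConfig] = None
) -> ReportBundle:
    """Run the full descriptive + inferential pipeline on a validated log."""
    config = config or AnalysisConfig()
    seed = config.seed

    rows = []
    for block, label, selector in category_table_rows():
        row = _slice_row(dataset, label, selector, config, f"cat:{block}:{label}")
        row["block"] = block
        rows.append(row)
    for block, selector in (
        ("Non-drug-related", NON_DRUG_RELATED),
        ("Drug-related", DRUG_RELATED),
    ):
        row = _slice_row(dataset, f"{block} (total)", selector, config, f"cat:{block}:total")
        row["block"] = block
        rows.append(row)
    category_table = pd.DataFrame(rows)[
        ["block", "slice", "n_tasks", "task_hours", "percent", "ci_low", "ci_high"]
    ]

    rows3 = []
    for sub, label, selector in who_how_table_cells():
        row = _slice_row(dataset, label, selector, config, f"whohow:{sub}:{label}")
        row["subcategory"] = sub
        rows3.append(row)
    who_how_table = pd.DataFrame(rows3)[
        ["subcategory", "slice", "n_tasks", "task_hours", "percent", "ci_low", "ci_high"]
    ]

    comp_stat = UnionProportionStatistic(tuple(config.composite_selectors()))
    comp_est = summarize_drug_list_process(dataset, config)
    comp_boot = bootstrap_ci(
        dataset,
        comp_stat,
        level=config.bootstrap_level,
        n_replicates=config.bootstrap_n_replicates,
        seed=derive_seed(seed, "composite"),
        cluster=config.bootstrap_cluster,
    )
    composite = {
        "percent": comp_est.as_percent,
        "percent_ci": (100.0 * comp_boot.ci_low, 100.0 * comp_boot.ci_high),
        "minutes_per_hour": comp_est.minutes_per_hour,
        "minutes_ci": (60.0 * comp_boot.ci_low, 60.0 * comp_boot.ci_high),
    }

    overall = interruption_rate(dataset)
    inter: dict = {
        "count": overall.event_count,
        "rate_per_hour": overall.rate_per_hour,
    }
    rate_boot = bootstrap_ci(
        dataset,
        InterruptionRateStatistic(),
        level=config.bootstrap_level,
        n_replicates=config.bootstrap_n_replicates,
        seed=derive_seed(seed, "interruption-rate"),
        cluster=config.bootstrap_cluster,
    )
    inter["rate_ci"] = (rate_boot.ci_low, rate_boot.ci_high)
    for name, sel in (("drug_related", DRUG_RELATED), ("non_drug_related", NON_DRUG_RELATED)):
        try:
            inter[f"rate_{name}"] = interruption_rate(dataset, sel).rate_per_hour
        except EstimatorError:
            inter[f"rate_{name}"] = float("nan")
    drug_doc = Selector.make(what="Documentation", subcategory="drug-related")
    try:
        inter["fraction_drug_documentation_tasks_interrupted"] = fraction_tasks_interrupted(
            dataset, drug_doc
        ).proportion
    except EstimatorError:
        inter["fraction_drug_documentation_tasks_interrupted"] = float("nan")
    try:
        inter["drug_documentation_interrupter_breakdown"] = interruption_reason_breakdown(
            dataset, drug_doc
        )
    except EstimatorError:
        inter["drug_documentation_interrupter_breakdown"] = {}

    multitask = {}
    for name, sel in (("drug_related", DRUG_RELATED), ("non_drug_related", NON_DRUG_RELATED)):
        try:
            multitask[name] = multitask_fraction(dataset, sel).as_percent
        except EstimatorError:
            multitask[name] = float("nan")

    mean_total, mean_new, mean_fu = patients_per_session(dataset)
    pat_boot = bootstrap_ci(
        dataset,
        SessionMeanStatistic("total"),
        level=config.bootstrap_level,
        n_replicates=config.bootstrap_n_replicates,
        seed=derive_seed(seed, "patients"),
        cluster=config.bootstrap_cluster,
    )
    patients = {
        "mean_total": mean_total,
        "mean_new": mean_new,
        "mean_followup": mean_fu,
        "total_ci": (pat_boot.ci_low, pat_boot.ci_high),
    }

    group_tests = {}
    for group_field in config.group_tests:
        try:
            res = monte_carlo_group_test(
                dataset,
                group_field,
                TimeProportionStatistic(DRUG_RELATED),
                n_permutations=config.n_permutations,
                seed=derive_seed(seed, "mc", group_field),
            )
            group_tests[group_field] = {
                "labels": res.group_labels,
                "difference": res.observed_statistic,
                "p_value": res.p_value,
            }
        except Exception as exc:  # noqa: BLE001 - reported, not fatal
            group_tests[group_field] = {"error": str(exc)}

    provenance = {
        "seed": seed,
        "bootstrap": {
            "n_replicates": config.bootstrap_n_replicates,
            "level": config.bootstrap_level,
            "cluster": config.bootstrap_cluster,
        },
        "test": {"n_permutations": config.n_permutations},
        "n_sessions": len(dataset.sessions),
        "n_records": len(dataset.records),
        "total_observation_hours": dataset.total_observation_hours,
    }
    return ReportBundle(
        category_table=category_table,
        who_how_table=who_how_table,
        composite=composite,
        interruptions=inter,
        multitask=multitask,
        patients=patients,
        group_tests=group_tests,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _fmt_table(df: pd.DataFrame) -> str:
    show = df.copy()
    show["task_hours"] = show["task_hours"].map(lambda v: f"{v:.1f}")
    for c in ("percent", "ci_low", "ci_high"):
        show[c] = show[c].map(
            lambda v: "-" if pd.isna(v) else f"{round_half_up(v, 1):.1f}"
        )
    return show.to_string(index=False)


def render_report(bundle: ReportBundle, out_dir: str | Path) -> Path:
    """Write the report bundle to ``out_dir``; returns the text report path.

    CSV/JSON outputs keep full precision; the text report uses display
    rounding.  Output is byte-identical across runs with identical inputs,
    settings and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.category_table.to_csv(out / "task_time_by_category.csv", index=False)
    bundle.who_how_table.to_csv(out / "task_time_by_who_how.csv", index=False)
    machine = {
        "composite_drug_list_process": bundle.composite,
        "interruptions": bundle.interruptions,
        "multitask_percent": bundle.multitask,
        "patients_per_session": bundle.patients,
        "group_tests": bundle.group_tests,
        "provenance": bundle.provenance,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(machine, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")

    lines = []
    prov = bundle.provenance
    lines.append("TIME-MOTION ANALYSIS REPORT")
    lines.append(
        f"settings: seed={prov['seed']} bootstrap(n={prov['bootstrap']['n_replicates']}, "
        f"level={prov['bootstrap']['level']}, cluster={prov['bootstrap']['cluster']}) "
        f"permutations={prov['test']['n_permutations']}"
    )
    lines.append(
        f"data: {prov['n_sessions']} sessions, {prov['n_records']} task records, "
        f"{prov['total_observation_hours']:.1f} h total observation time"
    )
    lines.append("")
    lines.append("== Distribution of task time (percent of total observation time) ==")
    lines.append(_fmt_table(bundle.category_table))
    lines.append("")
    lines.append("== Task time by who / how (percent of total observation time) ==")
    lines.append(_fmt_table(bundle.who_how_table))
    lines.append("")
    c = bundle.composite
    lines.append("== Composite drug-list process (obtain + document) ==")
    lines.append(
        f"percent of time: {round_half_up(c['percent'], 1):.1f} "
        f"(95% CI {round_half_up(c['percent_ci'][0], 1):.1f}, "
        f"{round_half_up(c['percent_ci'][1], 1):.1f})"
    )
    lines.append(
        f"minutes per hour: {round_half_up(c['minutes_per_hour'], 1):.1f} "
        f"(95% CI {round_half_up(c['minutes_ci'][0], 1):.1f}, "
        f"{round_half_up(c['minutes_ci'][1], 1):.1f})"
    )
    lines.append("")
    i = bundle.interruptions
    lines.append("== Interruptions ==")
    lines.append(
        f"count: {i['count']}; rate: {round_half_up(i['rate_per_hour'], 1):.1f}/h "
        f"(95% CI {round_half_up(i['rate_ci'][0], 1):.1f}, "
        f"{round_half_up(i['rate_ci'][1], 1):.1f})"
    )
    for key in ("rate_drug_related", "rate_non_drug_related"):
        v = i[key]
        lines.append(f"{key}: {'-' if pd.isna(v) else f'{round_half_up(v, 1):.1f}'}/h")
    frac = i["fraction_drug_documentation_tasks_interrupted"]
    lines.append(
        "drug documentation tasks interrupted: "
        + ("-" if pd.isna(frac) else f"{round_half_up(100 * frac, 1):.1f}%")
    )
    for what, share in i["drug_documentation_interrupter_breakdown"].items():
        lines.append(f"  interrupted by {what}: {round_half_up(100 * share, 1):.1f}%")
    lines.append("")
    lines.append("== Multitasking (percent of slice task time) ==")
    for k, v in bundle.multitask.items():
        lines.append(f"{k}: {'-' if pd.isna(v) else f'{round_half_up(v, 1):.1f}'}%")
    lines.append("")
    p = bundle.patients
    lines.append("== Patients per session ==")
    lines.append(
        f"total: {round_half_up(p['mean_total'], 1):.1f} "
        f"(95% CI {round_half_up(p['total_ci'][0], 1):.1f}, "
        f"{round_half_up(p['total_ci'][1], 1):.1f}); "
        f"new: {round_half_up(p['mean_new'], 1):.1f}; "
        f"follow-up: {round_half_up(p['mean_followup'], 1):.1f}"
    )
    lines.append("")
    lines.append("== Group contrasts (drug-related proportion, Monte Carlo) ==")
    for field_name, res in bundle.group_tests.items():
        if "error" in res:
            lines.append(f"{field_name}: not computed ({res['error']})")
        else:
            lines.append(
                f"{field_name}: {res['labels'][0]} - {res['labels'][1]} = "
                f"{res['difference'] * 100:+.2f} pp, p = {res['p_value']:.4f}"
            )
    lines.append("")
    report_path = out / "report.txt"
    report_path.write_text("\n".join(lines), encoding="utf-8")
    return report_path
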