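"""Markdown rendering of the metrics bundle (trigger-PPV and ADE tables)."""

from __future__ import annotations

from .metrics import CohortMetrics, format_ppv
from .triggers import TriggerDefinition, builtin_registry


def render_report(metrics: CohortMetrics,
                  registry: list[TriggerDefinition] | None = None) -> str:
    if registry is None:
        registry = builtin_registry()
    names = {d.trigger_id: d.name for d in registry}
    ades = {d.trigger_id: d.associated_ade for d in registry}
    lines = [
        "# Trigger-tool screening report",
        "",
        f"Admissions reviewed: {metrics.n_admissions}  ",
        f"Total patient-days: {metrics.total_patient_days}  ",
        f"Positive-trigger rate (γ): {metrics.gamma:.1f}%  ",
        f"Positive triggers: {metrics.total_hits} "
        f"({metrics.n_positive_triggers} of {len(metrics.per_trigger)} triggers fired)  ",
        f"Trigger-linked ADEs: {metrics.total_linked_ades} "
        f"({metrics.n_linked_triggers} triggers linked)  ",
        f"Overall PPV: {metrics.overall_ppv:.1f}%  ",
        f"Unique ADEs: {metrics.n_unique_ades}  ",
        f"Admissions with ADE: {metrics.pct_admissions_with_ade:.1f}%  ",
        f"ADEs per 100 admissions: {metrics.ades_per_100_admissions.rate:.1f} "
        f"(95% CI {metrics.ades_per_100_admissions.ci_low:.2f}-"
        f"{metrics.ades_per_100_admissions.ci_high:.2f}, "
        f"{metrics.ades_per_100_admissions.method})  ",
        f"ADEs per 1,000 patient-days: {metrics.ades_per_1000_patient_days.rate:.2f} "
        f"(95% CI {metrics.ades_per_1000_patient_days.ci_low:.2f}-"
        f"{metrics.ades_per_1000_patient_days.ci_high:.2f}, "
        f"{metrics.ades_per_1000_patient_days.method})  ",
        f"Admissions with serious ADE: {metrics.pct_admissions_with_sae:.1f}%  ",
        "",
        "## Triggers and PPV",
        "",
        "| No. | Trigger | Associated ADE | Positive triggers (n) | ADEs (n) | PPV (%) |",
        "|---|---|---|---|---|---|",
    ]
    for row in metrics.per_trigger:
        ppv = "n/a" if row.undefined else format_ppv(row.ppv)
        lines.append(
            f"| {row.trigger_id} | {names[row.trigger_id]} | {ades[row.trigger_id]} "
            f"| {row.positives} | {row.linked_ades} | {ppv} |")
    lines += [
        f"| **Subtotal** | | | {metrics.total_hits} | {metrics.total_linked_ades} "
        f"| {metrics.overall_ppv:.1f} |",
        "",
        "## ADE distributions",
        "",
        "| System/organ class | Count | % |",
        "|---|---|---|",
    ]
    for soc, (count, pct) in metrics.soc_distribution.items():
        lines.append(f"| {soc} | {count} | {pct:.1f} |")
    lines += ["", "| CTCAE severity | Count | % |", "|---|---|---|"]
    for grade, (count, pct) in sorted(metrics.severity_distribution.items()):
        lines.append(f"| {grade} | {count} | {pct:.1f} |")
    lines += ["", "| Causality | Count | % |", "|---|---|---|"]
    for cat, (count, pct) in metrics.causality_distribution.items():
        lines.append(f"| {cat} | {count} | {pct:.1f} |")
    lines += ["", "| Suspected-drug category | Mentions | % |", "|---|---|---|"]
    for cls, (count, pct) in metrics.drug_category_distribution.items():
        lines.append(f"| {cls} | {count} | {pct:.1f} |")
    lines.append("")
    return "\n".join(lines)
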