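"""Diagnostic grouping rules and group summary tables.

Children are assigned to one of three a-priori groups from their lifetime
diagnosis set: anxiety (at least one of GAD / SAD / SP and no
externalizing disorder), externalizing (at least one of ADHD / ODD / CD
and no anxiety disorder) or healthy control (no diagnosis at all).
Children comorbid for both an anxiety and an externalizing disorder, and
children whose only diagnoses fall outside both families (e.g. PTSD
alone), fit no a-priori group and are excluded.  A mood/other diagnosis
comorbid with exactly one family (e.g. MDD + ADHD) leaves the family
assignment unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

ANXIETY_DIAGNOSES = frozenset({"GAD", "SAD", "SP"})
EXTERNALIZING_DIAGNOSES = frozenset({"ADHD", "ODD", "CD"})
OTHER_DIAGNOSES = frozenset({"MDD", "DMDD", "OCD", "PTSD"})
DIAGNOSIS_REGISTRY = ANXIETY_DIAGNOSES | EXTERNALIZING_DIAGNOSES | OTHER_DIAGNOSES

GROUPS = ("healthy_control", "anxiety", "externalizing", "excluded")


@dataclass(frozen=True)
class DiagnosisRecord:
    participant_id: str
    diagnoses: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "diagnoses", frozenset(self.diagnoses))
        unknown = self.diagnoses - DIAGNOSIS_REGISTRY
        if unknown:
            raise ValueError(
                f"unknown diagnosis code(s) {sorted(unknown)} for "
                f"participant {self.participant_id!r}"
            )


@dataclass(frozen=True)
class GroupAssignment:
    participant_id: str
    group: str
    exclusion_reason: str = ""


def assign_group(rec: DiagnosisRecord) -> GroupAssignment:
    """Deterministic a-priori group assignment from the diagnosis set."""
    anx = bool(rec.diagnoses & ANXIETY_DIAGNOSES)
    ext = bool(rec.diagnoses & EXTERNALIZING_DIAGNOSES)
    if anx and ext:
        return GroupAssignment(
            rec.participant_id, "excluded",
            "comorbid anxiety and externalizing disorders",
        )
    if anx:
        return GroupAssignment(rec.participant_id, "anxiety")
    if ext:
        return GroupAssignment(rec.participant_id, "externalizing")
    if rec.diagnoses:
        return GroupAssignment(
            rec.participant_id, "excluded",
            f"diagnoses {sorted(rec.diagnoses)} fit no a-priori group",
        )
    return GroupAssignment(rec.participant_id, "healthy_control")


def summarize_groups(
    assignments: list[GroupAssignment],
    records: list[DiagnosisRecord] | None = None,
) -> pd.DataFrame:
    """Group summary table with integer-rounded percentages.

    One row per group (n, pct_of_sample over the non-excluded roster) and,
    when the diagnosis records are supplied, one row per diagnosis within
    its group (n, pct_of_sample, pct_within_group).  Percentages are
    100 x count / denominator, rounded to the nearest integer.
    """
    if not assignments:
        raise ValueError("empty assignment roster")
    included = [a for a in assignments if a.group != "excluded"]
    n_sample = len(included)
    if n_sample == 0:
        raise ValueError("all participants excluded; nothing to summarize")
    group_of = {a.participant_id: a.group for a in assignments}

    def pct(num: int, den: int) -> int:
        return int(round(100.0 * num / den)) if den else 0

    rows = []
    for group in ("healthy_control", "anxiety", "externalizing"):
        members = [a for a in included if a.group == group]
        rows.append(
            {
                "row": group,
                "group": group,
                "n": len(members),
                "pct_of_sample": pct(len(members), n_sample),
                "pct_within_group": pd.NA,
            }
        )
        if records is None:
            continue
        family = {"anxiety": ANXIETY_DIAGNOSES, "externalizing": EXTERNALIZING_DIAGNOSES}.get(group)
        if not family:
            continue
        counts: dict[str, int] = {}
        for rec in records:
            if group_of.get(rec.participant_id) != group:
                continue
            for dx in rec.diagnoses & family:
                counts[dx] = counts.get(dx, 0) + 1
        for dx in sorted(counts, key=lambda d: -counts[d]):
            rows.append(
                {
                    "row": dx,
                    "group": group,
                    "n": counts[dx],
                    "pct_of_sample": pct(counts[dx], n_sample),
                    "pct_within_group": pct(counts[dx], len(members)),
                }
            )
    return pd.DataFrame(rows)


def read_diagnosis_table(path) -> list[DiagnosisRecord]:
    """Delimited text: participant_id, semicolon-separated diagnosis codes."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        raw = row.get("diagnoses", "")
        codes = [] if pd.isna(raw) or not str(raw).strip() else str(raw).split(";")
        records.append(
            DiagnosisRecord(str(row["participant_id"]), frozenset(c.strip() for c in codes if c.strip()))
        )
    return records
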