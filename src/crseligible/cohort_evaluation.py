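"""Cohort-level reporting: prevalence tables, treatment cross-tabs, gaps,
and between-rule-set concordance.

All denominators follow the determinate-case convention: a patient enters a
proportion's denominator iff the relevant criterion (or composite) is
determinate for them under three-valued evaluation.  This is why a
composite's denominator can exceed a component's — a patient whose surgery
history settles the composite still counts there even if a laboratory leaf
is missing.  Patients with UNKNOWN composite verdicts, or with missing
treatment status, are excluded from cross-tabs, treatment gaps and
concordance, with exclusion counts logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .cohort_model import CohortTable, PatientRecord
from .criteria_engine import (Criterion, RuleSet, Verdict, evaluate,
                              walk_postorder)
from .stats import percent
from .tristate import FALSE, TRUE, UNKNOWN, TriState

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrevalenceRow:
    """One criterion's prevalence: met / evaluable, with the printed %."""

    criterion_id: str
    n_met: int
    n_evaluable: int
    pct: Optional[float]  # None (printed blank) when n_evaluable == 0

    def __post_init__(self):
        if not 0 <= self.n_met <= self.n_evaluable:
            raise ValueError(
                f"{self.criterion_id}: n_met {self.n_met} outside "
                f"[0, {self.n_evaluable}]")
        expected = (percent(self.n_met, self.n_evaluable)
                    if self.n_evaluable > 0 else None)
        if self.pct != expected:
            raise ValueError(
                f"{self.criterion_id}: pct {self.pct} does not recompute "
                f"from {self.n_met}/{self.n_evaluable}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: biologic initiated yes/no; columns: criteria met / not met."""

    a: int  # initiated, met
    b: int  # initiated, not met
    c: int  # not initiated, met
    d: int  # not initiated, not met

    def __post_init__(self):
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ConcordanceSummary:
    """Agreement between the two rule sets among dually-evaluable patients."""

    n_dual: int
    n_both: int
    n_neither: int
    n_only_2021: int
    n_only_2023: int
    agreement_pct: Optional[float]
    discordance_pct: Optional[float]

    def __post_init__(self):
        if self.n_both + self.n_neither + self.n_only_2021 + self.n_only_2023 \
                != self.n_dual:
            raise ValueError("concordance counts do not partition n_dual")


@dataclass(frozen=True)
class GapSummary:
    """Treatment gap for one rule set (determinate-case convention).

    ``pct_met_not_treated``: share of criteria-meeting patients not
    initiating a biologic.  ``pct_treated_not_met``: share of biologic
    initiators whose verdict is FALSE.  ``None`` = undefined (zero
    denominator).
    """

    ruleset_name: str
    pct_met_not_treated: Optional[float]
    pct_treated_not_met: Optional[float]


def evaluate_cohort(cohort: CohortTable, ruleset: RuleSet) -> List[Verdict]:
    """One verdict per record, in cohort order."""
    return [evaluate(ruleset, rec) for rec in cohort]


def _states_for(cohort: CohortTable, criterion: Criterion,
                ruleset: RuleSet) -> List[TriState]:
    return [criterion.evaluate(rec) for rec in cohort]


def prevalence_from_states(criterion_id: str,
                           states: Sequence[TriState]) -> PrevalenceRow:
    """Count TRUE / determinate over per-patient TriStates."""
    n_met = sum(1 for s in states if s is TRUE)
    n_evaluable = sum(1 for s in states if s.is_determinate())
    pct = percent(n_met, n_evaluable) if n_evaluable > 0 else None
    return PrevalenceRow(criterion_id, n_met, n_evaluable, pct)


def criterion_prevalence(cohort: CohortTable, criterion: Criterion,
                         ruleset: RuleSet) -> PrevalenceRow:
    """Prevalence of one criterion (leaf or composite) over the cohort."""
    return prevalence_from_states(
        criterion.id, _states_for(cohort, criterion, ruleset))


def indication_table(cohort: CohortTable,
                     ruleset: RuleSet) -> List[PrevalenceRow]:
    """One prevalence row per rule-tree node (leaves, sub-composites,
    overall), children before parents — the published table layout."""
    verdicts = evaluate_cohort(cohort, ruleset)
    rows = []
    for node in walk_postorder(ruleset.tree):
        states = [v.components[node.id] for v in verdicts]
        rows.append(prevalence_from_states(node.id, states))
    return rows


def crosstab_by_treatment(cohort: CohortTable,
                          ruleset: RuleSet) -> ContingencyTable2x2:
    """2x2 of biologic initiation against the composite verdict.

    Patients with an UNKNOWN composite verdict or missing treatment status
    are excluded (counts logged as warnings).
    """
    a = b = c = d = 0
    n_unknown = n_missing_tx = 0
    for rec, verdict in zip(cohort, evaluate_cohort(cohort, ruleset)):
        if rec.biologic_initiated is None:
            n_missing_tx += 1
            continue
        if verdict.overall is UNKNOWN:
            n_unknown += 1
            continue
        met = verdict.overall is TRUE
        if rec.biologic_initiated:
            a, b = (a + 1, b) if met else (a, b + 1)
        else:
            c, d = (c + 1, d) if met else (c, d + 1)
    if n_missing_tx:
        logger.warning("%s: %d patients excluded (missing biologic_initiated)",
                       ruleset.name, n_missing_tx)
    if n_unknown:
        logger.warning("%s: %d patients excluded (indeterminate verdict)",
                       ruleset.name, n_unknown)
    return ContingencyTable2x2(a, b, c, d)


def treatment_gap(cohort: CohortTable, ruleset: RuleSet,
                  table: Optional[ContingencyTable2x2] = None) -> GapSummary:
    """Treatment-gap percentages from the treatment cross-tab."""
    t = table if table is not None else crosstab_by_treatment(cohort, ruleset)
    if t.a + t.c > 0:
        met_not_treated: Optional[float] = percent(t.c, t.a + t.c)
    else:
        met_not_treated = None
        logger.warning("%s: no criteria-meeting determinate patients; "
                       "met-not-treated gap undefined", ruleset.name)
    if t.a + t.b > 0:
        treated_not_met: Optional[float] = percent(t.b, t.a + t.b)
    else:
        treated_not_met = None
        logger.warning("%s: no determinate biologic initiators; "
                       "treated-not-met gap undefined", ruleset.name)
    return GapSummary(ruleset.name, met_not_treated, treated_not_met)


def concordance(cohort: CohortTable,
                ruleset_2021: RuleSet,
                ruleset_2023: RuleSet) -> ConcordanceSummary:
    """Verdict agreement among patients determinate under BOTH rule sets."""
    n_both = n_neither = n_only_2021 = n_only_2023 = 0
    v21 = evaluate_cohort(cohort, ruleset_2021)
    v23 = evaluate_cohort(cohort, ruleset_2023)
    for a, b in zip(v21, v23):
        if not (a.evaluable and b.evaluable):
            continue
        if a.overall is TRUE and b.overall is TRUE:
            n_both += 1
        elif a.overall is FALSE and b.overall is FALSE:
            n_neither += 1
        elif a.overall is TRUE:
            n_only_2021 += 1
        else:
            n_only_2023 += 1
    n_dual = n_both + n_neither + n_only_2021 + n_only_2023
    if n_dual > 0:
        agreement = percent(n_both + n_neither, n_dual)
        discordance = percent(n_only_2021 + n_only_2023, n_dual)
    else:
        agreement = discordance = None
    return ConcordanceSummary(n_dual, n_both, n_neither, n_only_2021,
                              n_only_2023, agreement, discordance)
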