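"""Shared fixtures and the brute-force completion oracle.

The oracle evaluates a criterion tree by enumerating every boolean
completion of the missing leaves — the defining semantics that the Kleene
engine must reproduce — and stays deliberately independent of the engine's
own evaluation path (plain two-valued logic over explicit assignments).
"""

from itertools import product

import pytest
from hypothesis import settings

from crseligible.cohort_model import PatientRecord
from crseligible.criteria_engine import (AllOf, AnyOf, AtLeast, Flag,
                                         Threshold, leaves)
from crseligible.synthetic_cohort import default_config, simulate_cohort
from crseligible.tristate import FALSE, TRUE, UNKNOWN

settings.register_profile("ci", derandomize=True, max_examples=150)
settings.load_profile("ci")


def make_record(**kwargs) -> PatientRecord:
    kwargs.setdefault("patient_id", "P1")
    return PatientRecord(**kwargs)


def bool_eval(node, assignment):
    """Two-valued evaluation of a tree under a complete leaf assignment."""
    if isinstance(node, (Threshold, Flag)):
        return assignment[node.id]
    if isinstance(node, AllOf):
        return all(bool_eval(c, assignment) for c in node.children)
    if isinstance(node, AnyOf):
        return any(bool_eval(c, assignment) for c in node.children)
    if isinstance(node, AtLeast):
        return sum(bool_eval(c, assignment) for c in node.children) >= node.k
    raise TypeError(node)


def completion_oracle(tree, record):
    """Three-way summary of brute-force evaluation over all completions of
    the missing leaves: TRUE iff every completion is true, FALSE iff none
    is, UNKNOWN otherwise."""
    fixed, unknown_ids = {}, []
    for leaf in leaves(tree):
        state = leaf.evaluate(record)
        if state is UNKNOWN:
            unknown_ids.append(leaf.id)
        else:
            fixed[leaf.id] = state is TRUE
    outcomes = set()
    for bits in product((False, True), repeat=len(unknown_ids)):
        assignment = dict(fixed)
        assignment.update(zip(unknown_ids, bits))
        outcomes.add(bool_eval(tree, assignment))
        if outcomes == {False, True}:
            return UNKNOWN
    return TRUE if outcomes == {True} else FALSE


@pytest.fixture(scope="session")
def large_default_cohort():
    """One n=20000 default-config cohort shared by the calibration tests."""
    return simulate_cohort(default_config(n=20000, seed=20210))
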