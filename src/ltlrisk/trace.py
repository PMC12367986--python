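"""Replayable decision traces.

Every hazard-assessment routing decision is recorded as a branch with a
named predicate and the concrete values the predicate saw.  A trace can be
replayed later: each predicate is re-evaluated on the stored inputs and must
reproduce the recorded outcome.  This makes assessments auditable — the JSON
report contains enough information to verify every branch that fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Dict, List


def _is_true(x: object) -> bool:
    return bool(x)


def _equals(a: object, b: object) -> bool:
    return a == b


# Registry of branch predicates. Predicates must be pure functions of their
# keyword inputs so that replay is deterministic.
PREDICATES: Dict[str, Callable[..., bool]] = {
    "is_true": _is_true,
    "equals": _equals,
    "greater": lambda a, b: a > b,
    "greater_equal": lambda a, b: a >= b,
    "less": lambda a, b: a < b,
    "less_equal": lambda a, b: a <= b,
    "in_set": lambda x, options: x in options,
    "is_none": lambda x: x is None,
    "not_none": lambda x: x is not None,
    "non_empty": lambda x: len(x) > 0,
    "empty": lambda x: len(x) == 0,
}


@dataclass(frozen=True)
class Branch:
    """One decision-tree branch that fired, with its evidence."""

    branch_id: str
    predicate: str
    inputs: Dict[str, Any]
    outcome: bool
    rationale: str

    def replay(self) -> bool:
        """Re-evaluate the predicate on the stored inputs."""
        return PREDICATES[self.predicate](**self.inputs) == self.outcome

    def to_dict(self) -> Dict[str, Any]:
        return {
            "branch": self.branch_id,
            "predicate": self.predicate,
            "inputs": self.inputs,
            "outcome": self.outcome,
            "rationale": self.rationale,
        }


@dataclass
class DecisionTrace:
    """Ordered record of the branches a decision tree evaluated."""

    branches: List[Branch] = field(default_factory=list)

    def record(
        self,
        branch_id: str,
        predicate: str,
        rationale: str = "",
        **inputs: Any,
    ) -> bool:
        """Evaluate a registered predicate, record the branch, return the outcome."""
        if predicate not in PREDICATES:
            raise KeyError(f"unknown trace predicate: {predicate!r}")
        outcome = bool(PREDICATES[predicate](**inputs))
        self.branches.append(
            Branch(branch_id, predicate, dict(inputs), outcome, rationale)
        )
        return outcome

    def note(self, branch_id: str, rationale: str) -> None:
        """Record an unconditional annotation (always-true branch)."""
        self.record(branch_id, "is_true", rationale, x=True)

    def replay(self) -> bool:
        """True iff every recorded branch re-evaluates to its stored outcome."""
        return all(b.replay() for b in self.branches)

    def to_list(self) -> List[Dict[str, Any]]:
        return [b.to_dict() for b in self.branches]

    def __iter__(self):
        return iter(self.branches)

    def __len__(self) -> int:
        return len(self.branches)
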