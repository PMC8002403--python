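"""Empirical solubility and synthesis rule checks.

Each rule is a small predicate over the sequence producing a failed flag plus
human-readable evidence (the matched span or the computed quantity). The more
rules a peptide fails, the lower its odds of being synthesized and kept in
solution — the counts feed the per-peptide property report.

Solubility rules (v1):

* ``S1`` — charged residues (D, E, K, R, H) exceed 45% of the sequence;
* ``S2`` — hydrophobic residues (A, I, L, M, F, W, V, Y) exceed 45%;
* ``S3`` — absolute net charge at pH 7 exceeds 1.

Synthesis rules (v1, each toggleable):

* ``T1`` — four or more identical consecutive residues;
* ``T2`` — aspartate-mediated cleavage motif (DG or DP) present;
* ``T3`` — N-terminal Gln or Asn (cyclization / deamidation risk);
* ``T4`` — hydrophobic stretch: more than 75% of the 5-residue windows
  contain no charged residue;
* ``T5`` — two or more oxidation-prone residues (Met, Cys, Trp combined).

All thresholds use strict inequality ("exceeds" / "more than"). Histidine
counts as charged for the categorical rules while contributing only
fractionally to the continuous net charge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable

from . import core, physchem
from .core import Peptide

__all__ = [
    "Rule",
    "RuleResult",
    "RuleReport",
    "SOLUBILITY_RULES",
    "SYNTHESIS_RULES",
    "check_solubility_rules",
    "check_synthesis_rules",
    "check_all_rules",
]

CHARGED_FRACTION_LIMIT = 0.45
HYDROPHOBIC_FRACTION_LIMIT = 0.45
NET_CHARGE_LIMIT = 1.0
REPEAT_RUN_LIMIT = 4          # run length that triggers T1
WINDOW = 5                    # residue window for T4
CHARGE_FREE_WINDOW_LIMIT = 0.75
OXIDATION_PRONE = frozenset("MCW")
OXIDATION_COUNT_LIMIT = 2


@dataclass(frozen=True)
class Rule:
    id: str
    statement: str
    category: str  # "solubility" | "synthesis"
    check: Callable[[Peptide], tuple[bool, str]]


@dataclass(frozen=True)
class RuleResult:
    rule_id: str
    statement: str
    category: str
    failed: bool
    evidence: str


@dataclass(frozen=True)
class RuleReport:
    results: tuple[RuleResult, ...]

    @property
    def n_solubility_failed(self) -> int:
        return sum(r.failed for r in self.results
                   if r.category == "solubility")

    @property
    def n_synthesis_failed(self) -> int:
        return sum(r.failed for r in self.results
                   if r.category == "synthesis")

    def to_records(self) -> list[dict]:
        return [vars(r).copy() for r in self.results]


def _charged_fraction(p: Peptide) -> tuple[bool, str]:
    frac = sum(r.charged for r in p.records) / len(p)
    return frac > CHARGED_FRACTION_LIMIT, f"charged fraction {frac:.3f}"


def _hydrophobic_fraction(p: Peptide) -> tuple[bool, str]:
    frac = sum(r.hydrophobic for r in p.records) / len(p)
    return frac > HYDROPHOBIC_FRACTION_LIMIT, f"hydrophobic fraction {frac:.3f}"


def _net_charge_magnitude(p: Peptide) -> tuple[bool, str]:
    q = physchem.net_charge(p, 7.0)
    return abs(q) > NET_CHARGE_LIMIT, f"net charge at pH 7 = {q:+.2f}"


def _consecutive_repeat(p: Peptide) -> tuple[bool, str]:
    m = re.search(r"(.)\1{%d,}" % (REPEAT_RUN_LIMIT - 1), p.letters)
    if m:
        return True, f"run {m.group(0)!r} at position {m.start() + 1}"
    return False, "no run of %d identical residues" % REPEAT_RUN_LIMIT


def _asp_cleavage_motif(p: Peptide) -> tuple[bool, str]:
    m = re.search(r"D[GP]", p.letters)
    if m:
        return True, f"motif {m.group(0)} at position {m.start() + 1}"
    return False, "no DG/DP motif"


def _nterm_gln_asn(p: Peptide) -> tuple[bool, str]:
    first = p.letters[0]
    if first in "QN":
        return True, f"N-terminal {first}"
    return False, f"N-terminal {first}"


def _hydrophobic_stretch(p: Peptide) -> tuple[bool, str]:
    letters = p.letters
    charged = [rec.charged for rec in p.records]
    w = min(WINDOW, len(letters))
    windows = [charged[i:i + w] for i in range(len(letters) - w + 1)]
    frac = sum(not any(win) for win in windows) / len(windows)
    return (frac > CHARGE_FREE_WINDOW_LIMIT,
            f"{frac:.2f} of {w}-residue windows charge-free")


def _oxidation_prone(p: Peptide) -> tuple[bool, str]:
    n = sum(letter in OXIDATION_PRONE for letter in p.letters)
    return n >= OXIDATION_COUNT_LIMIT, f"{n} oxidation-prone residues (M/C/W)"


SOLUBILITY_RULES: tuple[Rule, ...] = (
    Rule("S1", "charged residues exceed 45% of the sequence",
         "solubility", _charged_fraction),
    Rule("S2", "hydrophobic residues exceed 45% of the sequence",
         "solubility", _hydrophobic_fraction),
    Rule("S3", "absolute net charge at pH 7 is more than 1",
         "solubility", _net_charge_magnitude),
)

SYNTHESIS_RULES: tuple[Rule, ...] = (
    Rule("T1", "four or more identical consecutive residues",
         "synthesis", _consecutive_repeat),
    Rule("T2", "aspartate cleavage motif DG or DP present",
         "synthesis", _asp_cleavage_motif),
    Rule("T3", "N-terminal Gln or Asn", "synthesis", _nterm_gln_asn),
    Rule("T4", "more than 75% of 5-residue windows lack a charged residue",
         "synthesis", _hydrophobic_stretch),
    Rule("T5", "two or more oxidation-prone residues (M, C, W)",
         "synthesis", _oxidation_prone),
)


def _evaluate(p: Peptide | str, rules: tuple[Rule, ...]) -> RuleReport:
    p = core._as_peptide(p)
    results = []
    for rule in rules:
        failed, evidence = rule.check(p)
        results.append(RuleResult(rule.id, rule.statement, rule.category,
                                  failed, evidence))
    return RuleReport(tuple(results))


def check_solubility_rules(p: Peptide | str) -> RuleReport:
    """Evaluate the registered solubility rules."""
    return _evaluate(p, SOLUBILITY_RULES)


def check_synthesis_rules(p: Peptide | str) -> RuleReport:
    """Evaluate the registered synthesis rules."""
    return _evaluate(p, SYNTHESIS_RULES)


def check_all_rules(p: Peptide | str,
                    rules: tuple[Rule, ...] | None = None) -> RuleReport:
    """Evaluate all registered rules (or an explicit subset, any order).

    Evaluation is pure — the report depends only on the sequence, never on
    registration order.
    """
    if rules is None:
        rules = SOLUBILITY_RULES + SYNTHESIS_RULES
    return _evaluate(p, rules)
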