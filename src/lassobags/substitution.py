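"""Knowledge-guided substitution of selected covariates by bag members.

Given the stage-1 selected set S, its bags and the expert's binary
relevance labels, each selected covariate is resolved by fixed rules:

1. a biologically relevant owner is always kept;
2. otherwise, a single relevant bag member replaces the owner;
3. with several relevant members, the best-scoring one wins — largest
   correlation with the owner for B1/B2 bags, smallest replacement MSE
   for B3 bags;
4. with no relevant member, the owner is retained.

A relevant variable pulled in from several bags (or coinciding with a
kept owner) appears only once in the final model; later occurrences are
recorded as collapsed duplicates, so the final model can only get
sparser.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bags import RULE_B3, BagCollection, shortlist_union
from .containers import Dataset, RelevanceMap
from .penalized import SelectionResult

__all__ = ["SubstitutionRecord", "SubstitutionResult", "apply_substitutions"]

KEPT_RELEVANT = "kept_relevant"
KEPT_NO_CANDIDATE = "kept_no_candidate"
SWITCHED = "switched"
COLLAPSED_DUPLICATE = "collapsed_duplicate"


@dataclass
class SubstitutionRecord:
    """Audit entry for one selected covariate."""

    owner: str
    outcome: str
    replacement: str | None = None
    decided_by: str = "n/a"
    score: float | None = None


@dataclass
class SubstitutionResult:
    records: list[SubstitutionRecord]
    final_variables: list[str]

    def record_for(self, owner: str) -> SubstitutionRecord:
        for r in self.records:
            if r.owner == owner:
                return r
        raise KeyError(owner)


def apply_substitutions(
    S: SelectionResult,
    bags: BagCollection,
    relevance: RelevanceMap,
    data: Dataset | None = None,
) -> SubstitutionResult:
    """Resolve every selected covariate by the substitution rules.

    ``relevance`` must label every shortlist variable (owners and all bag
    members); an unlabelled variable aborts with its id, signalling an
    incomplete elicitation.  ``data`` is unused by the rules themselves
    (bag scores decide everything) and accepted only for interface
    symmetry with bag construction.
    """
    if set(bags.bags) != set(S.selected):
        raise ValueError("bags were built from a different selected set")
    missing = relevance.missing_from(shortlist_union(bags))
    if missing:
        raise ValueError(
            f"relevance label missing for {missing[0]!r} "
            f"({len(missing)} unlabelled shortlist variables): incomplete elicitation"
        )

    many_rule = "min_mse" if bags.rule == RULE_B3 else "max_correlation"
    records: list[SubstitutionRecord] = []
    final: list[str] = []
    taken: set[str] = set()
    for owner in S.selected:
        bag = bags.bags[owner]
        if relevance[owner]:
            choice, outcome, decided, score = owner, KEPT_RELEVANT, "n/a", None
        else:
            rel_members = [(m, s) for m, s in bag.members if relevance[m]]
            if not rel_members:
                choice, outcome, decided, score = owner, KEPT_NO_CANDIDATE, "n/a", None
            elif len(rel_members) == 1:
                (choice, score), outcome, decided = rel_members[0], SWITCHED, "only_candidate"
            else:
                # members are stored best-first, so the first relevant one
                # is the winner under either rule
                (choice, score), outcome, decided = rel_members[0], SWITCHED, many_rule
        if choice in taken:
            records.append(
                SubstitutionRecord(owner, COLLAPSED_DUPLICATE, choice, decided, score)
            )
            continue
        taken.add(choice)
        final.append(choice)
        records.append(
            SubstitutionRecord(
                owner, outcome, choice if outcome == SWITCHED else None, decided, score
            )
        )
    return SubstitutionResult(records, final)
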