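"""Mitochondrial screening by majority vote over three localization tools.

A protein is called mitochondrial when at least two of the three external
predictors (by default BUSCA, TargetP-2.0 and MitoFates) place it in the
organelle.  Tool outputs are consumed as pre-tabulated booleans
("predicted compartment == mitochondrion"); proteins lacking a vote from
any tool are excluded and reported, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ToolVoteTable

N_TOOLS = 3
MAJORITY = 2


@dataclass(frozen=True)
class EnsembleDecision:
    protein_id: str
    votes: dict[str, bool]
    is_mitochondrial: bool
    n_positive: int

    def __post_init__(self) -> None:
        if self.n_positive != sum(self.votes.values()):
            raise ValueError("n_positive inconsistent with votes")
        if self.is_mitochondrial != (self.n_positive >= MAJORITY):
            raise ValueError("decision inconsistent with the 2-of-3 rule")


def majority_vote(votes: tuple[bool, bool, bool]) -> bool:
    """True iff at least 2 of exactly 3 votes are positive."""
    votes = tuple(votes)
    if len(votes) != N_TOOLS:
        raise ValueError(f"expected exactly {N_TOOLS} votes, got {len(votes)}")
    if not all(isinstance(v, (bool,)) for v in votes):
        raise TypeError("votes must be booleans")
    return sum(votes) >= MAJORITY


def screen_proteome(
    table: ToolVoteTable,
) -> tuple[list[EnsembleDecision], list[str]]:
    """One decision per fully-voted protein; incomplete proteins are rejects.

    Deterministic and independent of row order: proteins are emitted in
    first-appearance order, rejects (proteins with fewer than three tool
    votes) separately.
    """
    decisions: list[EnsembleDecision] = []
    rejects: list[str] = []
    for pid in table.proteins():
        votes = table.votes_for(pid)
        if set(votes) != set(table.tools):
            rejects.append(pid)
            continue
        ordered = {tool: votes[tool] for tool in table.tools}
        n_pos = sum(ordered.values())
        decisions.append(
            EnsembleDecision(
                protein_id=pid,
                votes=ordered,
                is_mitochondrial=n_pos >= MAJORITY,
                n_positive=n_pos,
            )
        )
    return decisions, rejects


def write_decisions(path, decisions: list[EnsembleDecision]) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tn_positive\tis_mitochondrial\n")
        for d in decisions:
            fh.write(f"{d.protein_id}\t{d.n_positive}\t{str(d.is_mitochondrial).lower()}\n")


def write_rejects(path, rejects: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\treason\n")
        for pid in rejects:
            fh.write(f"{pid}\tincomplete_votes\n")
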