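"""Validate a consensus ploidy signature against an external cohort.

The consensus up/down sets are matched direction-concordantly against the
external cohort's up/down DEG lists over the shared tested universe, and
each directional overlap is scored with a hypergeometric upper-tail p.
Direction-discordant overlaps (consensus-up genes that move down in the
external cohort, and vice versa) are reported informationally but do not
count as matches.
"""

from __future__ import annotations

from dataclasses import dataclass

from .consensus import ConsensusSet
from .enrichment import hypergeom_upper_tail
from .errors import ValidationError


@dataclass
class OverlapResult:
    """Direction-concordant matches of a consensus signature."""

    matched_up: frozenset[str]
    matched_down: frozenset[str]
    p_up: float
    p_down: float
    discordant_up: frozenset[str]  # consensus-up but external-down
    discordant_down: frozenset[str]  # consensus-down but external-up
    universe_size: int

    @property
    def n_matched_up(self) -> int:
        return len(self.matched_up)

    @property
    def n_matched_down(self) -> int:
        return len(self.matched_down)


def match_signature(
    consensus: ConsensusSet,
    external_up: set[str],
    external_down: set[str],
    universe: set[str],
) -> OverlapResult:
    """Match consensus sets against an external cohort's DEG lists.

    All sets are restricted to ``universe`` (the genes testable in both
    studies) before counting; the hypergeometric p for each direction uses
    that universe as the background.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty shared universe")
    cons_up = set(consensus.up) & universe
    cons_down = set(consensus.down) & universe
    ext_up = set(external_up) & universe
    ext_down = set(external_down) & universe

    matched_up = cons_up & ext_up
    matched_down = cons_down & ext_down
    N = len(universe)
    p_up = (
        hypergeom_upper_tail(N, len(ext_up), len(cons_up), len(matched_up))
        if cons_up and ext_up
        else 1.0
    )
    p_down = (
        hypergeom_upper_tail(N, len(ext_down), len(cons_down), len(matched_down))
        if cons_down and ext_down
        else 1.0
    )
    return OverlapResult(
        matched_up=frozenset(matched_up),
        matched_down=frozenset(matched_down),
        p_up=p_up,
        p_down=p_down,
        discordant_up=frozenset(cons_up & ext_down),
        discordant_down=frozenset(cons_down & ext_up),
        universe_size=N,
    )
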