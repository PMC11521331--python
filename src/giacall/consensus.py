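"""Consensus determination from the three method calls.

Rule 1: if any population label is shared by at least two of {k-NN call,
correlation call, discrete admixture call}, the consensus is that label.
Rule 2: otherwise, if the two PC-based calls disagree and no admixture
fraction exceeds the majority threshold, the consensus is Mixed Ancestry.
Rule 3: otherwise (no two methods align while a majority admixture
fraction is present), the consensus is Inconclusive.  The special calls
MIXED_ANCESTRY (correlation tie) and NO_MAJORITY (admixture) never match a
population label under Rule 1.  Individual method results are always
carried in the output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .admixture import AdmixtureModel, AdmixtureResult, discrete_admixture_call
from .classify import MIXED_ANCESTRY, NO_MAJORITY
from .config import POPULATIONS, WorkflowConfig
from .errors import ContractError

INCONCLUSIVE = "INCONCLUSIVE"

_SPECIAL = {MIXED_ANCESTRY, NO_MAJORITY}


@dataclass
class ConsensusResult:
    """The three method calls, the fractions, and the final GIA."""

    knn_call: str
    corr_call: str
    admixture_call: str
    fractions: AdmixtureResult
    consensus: str


def consensus_call(knn: str, corr: str, fractions: AdmixtureResult,
                   model: AdmixtureModel,
                   cfg: WorkflowConfig) -> ConsensusResult:
    """Apply the two-of-three consensus rules to the method outputs."""
    if knn not in POPULATIONS:
        raise ContractError(f"invalid k-NN call: {knn!r}")
    if corr not in POPULATIONS and corr != MIXED_ANCESTRY:
        raise ContractError(f"invalid correlation call: {corr!r}")
    adm = discrete_admixture_call(fractions, model, cfg)

    votes = Counter(c for c in (knn, corr, adm) if c not in _SPECIAL)
    top = votes.most_common(1)
    if top and top[0][1] >= 2:
        consensus = top[0][0]
    elif adm == NO_MAJORITY:
        # PC-based calls disagree (Rule 1 would have fired otherwise) and
        # all fractions are below the majority threshold.
        consensus = MIXED_ANCESTRY
    else:
        consensus = INCONCLUSIVE
    return ConsensusResult(knn_call=knn, corr_call=corr, admixture_call=adm,
                           fractions=fractions, consensus=consensus)
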