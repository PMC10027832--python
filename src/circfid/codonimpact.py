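"""Synonymous/non-synonymous impact of the 12 substitution types.

The genetic code concentrates its degeneracy at the wobble (third) codon
position, and does so asymmetrically: two-codon amino acids invariably pair
C with U, or G with A, in the wobble slot.  A C>U or G>A transcription error
striking the wobble base therefore usually leaves the protein untouched.
This module enumerates, over all 64 codons and all three positions, what
each of the 12 directed substitutions can do to the encoded amino acid, and
relates the resulting synonymous:non-synonymous ratio to a measured error
spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .quantify import SUBSTITUTION_TYPES, SubstitutionSpectrum

RNA_BASES = "ACGU"
STOP = "*"


def standard_genetic_code() -> Dict[str, str]:
    """The standard (NCBI table 1) genetic code over RNA codons; stops are '*'."""
    table = CodonTable.unambiguous_rna_by_id[1]
    code = dict(table.forward_table)
    for codon in table.stop_codons:
        code[codon] = STOP
    return code


def _validate_code(code: Mapping[str, str]) -> None:
    expected = {"".join(c) for c in product(RNA_BASES, repeat=3)}
    if set(code) != expected:
        missing = expected - set(code)
        extra = set(code) - expected
        raise ValueError(
            f"genetic code table must cover exactly the 64 RNA codons "
            f"(missing {sorted(missing)[:3]}..., extra {sorted(extra)[:3]}...)"
        )


@dataclass(frozen=True)
class SubstitutionImpact:
    """What one substitution type can do across the whole codon table.

    ``n_opportunities`` counts codon-position pairs holding the source base
    (48 per type under any code: 64 codons x 3 positions / 4 bases).  A
    change is synonymous when the encoded amino acid is unchanged (stop to
    stop included), non-synonymous otherwise; gaining a stop is a subclass
    of non-synonymous, losing one is non-synonymous as well.
    """

    sub_type: str
    n_opportunities: int
    n_synonymous: int
    n_nonsynonymous: int
    n_stop_gained: int

    @property
    def ratio(self) -> float:
        """Synonymous : non-synonymous ratio (stop-gained in the denominator)."""
        if self.n_nonsynonymous == 0:
            return float("inf")
        return self.n_synonymous / self.n_nonsynonymous


def impact_table(
    code: Optional[Mapping[str, str]] = None,
) -> Dict[str, SubstitutionImpact]:
    """Enumerate the impact of each of the 12 substitution types.

    For every codon and every position holding the source base, the target
    base is substituted and the outcome classified against ``code`` (the
    standard code by default).  Codon usage is deliberately not weighted:
    the table describes the potential changes offered by the code itself.
    """
    if code is None:
        code = standard_genetic_code()
    _validate_code(code)
    out: Dict[str, SubstitutionImpact] = {}
    for sub_type in SUBSTITUTION_TYPES:
        src, dst = sub_type[0], sub_type[2]
        n_opp = n_syn = n_non = n_stop = 0
        for codon, aa in code.items():
            for pos in range(3):
                if codon[pos] != src:
                    continue
                n_opp += 1
                mutated = codon[:pos] + dst + codon[pos + 1 :]
                new_aa = code[mutated]
                if new_aa == aa:
                    n_syn += 1
                else:
                    n_non += 1
                    if new_aa == STOP:
                        n_stop += 1
        out[sub_type] = SubstitutionImpact(
            sub_type=sub_type,
            n_opportunities=n_opp,
            n_synonymous=n_syn,
            n_nonsynonymous=n_non,
            n_stop_gained=n_stop,
        )
    return out


def impact_frame(impacts: Mapping[str, SubstitutionImpact]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sub_type": t,
                "n_opportunities": impacts[t].n_opportunities,
                "n_synonymous": impacts[t].n_synonymous,
                "n_nonsynonymous": impacts[t].n_nonsynonymous,
                "n_stop_gained": impacts[t].n_stop_gained,
                "syn_nonsyn_ratio": impacts[t].ratio,
            }
            for t in SUBSTITUTION_TYPES
        ]
    )


@dataclass
class RateImpactAssociation:
    table: pd.DataFrame  # sub_type, rate, syn_nonsyn_ratio
    spearman_rho: float
    spearman_p: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.spearman_rho)


def rate_vs_impact(
    spectrum: SubstitutionSpectrum,
    impacts: Optional[Mapping[str, SubstitutionImpact]] = None,
) -> RateImpactAssociation:
    """Pair measured per-type error rates with the code's syn:nonsyn ratios.

    Errors with a higher chance of changing the protein (lower ratio) are
    expected to occur at lower rates; the association is summarised by a
    Spearman rank correlation, chosen because the claim is monotone, not
    linear.  With fewer than 3 types showing a defined nonzero rate the
    correlation is reported as NaN while the paired table is still emitted.
    """
    if impacts is None:
        impacts = impact_table()
    rows = []
    for t in SUBSTITUTION_TYPES:
        rate = spectrum.rate(t)
        rows.append(
            {"sub_type": t, "rate": rate, "syn_nonsyn_ratio": impacts[t].ratio}
        )
    table = pd.DataFrame(rows)
    usable = table.dropna(subset=["rate"])
    nonzero = usable[usable["rate"] > 0]
    if len(nonzero) < 3 or usable["rate"].nunique() < 2:
        return RateImpactAssociation(table, float("nan"), float("nan"))
    rho, p = stats.spearmanr(usable["rate"], usable["syn_nonsyn_ratio"])
    return RateImpactAssociation(table, float(rho), float(p))
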