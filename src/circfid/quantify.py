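"""Error rates, substitution spectra, indel rates and replicate statistics.

Rates are reported per polymerase class as the unweighted mean of the
per-replicate rates (errors / surveyed bases within each biologically
independent replicate) with the standard error of that mean.  The
substitution spectrum resolves the 12 directed base changes in transcript
orientation (RNA alphabet, e.g. ``G>A`` means the transcript carries A where
the sense reference has G), each normalised by its own opportunity — the
surveyed bases whose reference is the source base.  Group comparisons use
unpaired two-tailed Welch's t-tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .callerrors import CandidateError, SurveyLedger
from .config import PolymeraseClass

#: The 12 directed substitution types, transcript orientation, RNA alphabet.
SUBSTITUTION_TYPES = (
    "A>C", "A>G", "A>U",
    "C>A", "C>G", "C>U",
    "G>A", "G>C", "G>U",
    "U>A", "U>C", "U>G",
)

_DNA2RNA = {"A": "A", "C": "C", "G": "G", "T": "U", "U": "U"}


def substitution_type(ref_base: str, alt_base: str) -> str:
    """Canonical type label from transcript-orientation DNA or RNA bases."""
    ref = _DNA2RNA.get(ref_base.upper())
    alt = _DNA2RNA.get(alt_base.upper())
    if ref is None or alt is None or ref == alt:
        raise ValueError(f"not a substitution: {ref_base}>{alt_base}")
    return f"{ref}>{alt}"


@dataclass
class ErrorRateEstimate:
    """Per-class error rate across replicates (mean +/- SEM, errors/bp)."""

    group: str
    pol_class: PolymeraseClass
    n_errors: List[int]
    n_bases: List[int]

    @property
    def n_replicates(self) -> int:
        return len(self.n_errors)

    @property
    def rates(self) -> List[float]:
        return [
            e / b if b else float("nan") for e, b in zip(self.n_errors, self.n_bases)
        ]

    @property
    def defined(self) -> bool:
        return any(b > 0 for b in self.n_bases)

    @property
    def mean_rate(self) -> float:
        rates = [r for r in self.rates if not math.isnan(r)]
        return float(np.mean(rates)) if rates else float("nan")

    @property
    def sem(self) -> float:
        rates = [r for r in self.rates if not math.isnan(r)]
        if len(rates) < 2:
            return 0.0
        return float(np.std(rates, ddof=1) / math.sqrt(len(rates)))


@dataclass
class SubstitutionSpectrum:
    """Counts, opportunities and per-type rates for the 12 substitutions."""

    counts: Dict[str, int]
    opportunities: Dict[str, int]

    def rate(self, sub_type: str) -> float:
        opp = self.opportunities[sub_type]
        return self.counts[sub_type] / opp if opp else float("nan")

    @property
    def total_errors(self) -> int:
        return sum(self.counts.values())

    @property
    def total_opportunities(self) -> int:
        # each surveyed base is an opportunity for 3 alternative bases
        return sum(self.opportunities.values()) // 3

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sub_type": list(SUBSTITUTION_TYPES),
                "count": [self.counts[t] for t in SUBSTITUTION_TYPES],
                "opportunity_bases": [
                    self.opportunities[t] for t in SUBSTITUTION_TYPES
                ],
                "rate": [self.rate(t) for t in SUBSTITUTION_TYPES],
            }
        )


@dataclass(frozen=True)
class WelchResult:
    mean_a: float
    mean_b: float
    var_a: float
    var_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p: float
    degenerate: bool = False


def compute_rates(
    ledgers: Sequence[SurveyLedger], group: str = ""
) -> Dict[PolymeraseClass, ErrorRateEstimate]:
    """Cross-replicate rate estimates per polymerase class.

    Each ledger is one biologically independent replicate.  Replicates with
    zero surveyed bases for a class are excluded from that class's mean
    rather than divided; a class with no surveyed bases anywhere is flagged
    undefined (``defined`` False, NaN mean).
    """
    if not ledgers:
        raise ValueError("at least one replicate ledger is required")
    out = {}
    for pc in PolymeraseClass:
        errors = [ledger.classes[pc].n_errors for ledger in ledgers]
        bases = [ledger.classes[pc].n_bases for ledger in ledgers]
        out[pc] = ErrorRateEstimate(
            group=group, pol_class=pc, n_errors=errors, n_bases=bases
        )
    return out


def compute_spectrum(
    errors: Iterable[CandidateError], ledger: SurveyLedger
) -> SubstitutionSpectrum:
    """12-type spectrum from confirmed substitution errors and the ledger.

    Opportunities for type X>Y are the surveyed bases whose (transcript
    orientation) reference is X, summed over classes; consequently the type
    counts sum to the ledger numerator and each source base's opportunities
    are shared by its three alternative targets.
    """
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    for err in errors:
        if err.kind != "substitution" or not err.confirmed:
            continue
        counts[substitution_type(err.ref_base, err.alt_base)] += 1
    den_by_ref = np.zeros(4, dtype=np.int64)
    for tally in ledger.classes.values():
        den_by_ref += tally.den_by_ref
    opportunities = {}
    for t in SUBSTITUTION_TYPES:
        src = t[0]
        src_dna_idx = "ACGU".index(src)  # A,C,G,U(=T) share index order
        opportunities[t] = int(den_by_ref[src_dna_idx])
    return SubstitutionSpectrum(counts=counts, opportunities=opportunities)


def welch_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> WelchResult:
    """Unpaired two-tailed Welch's t-test with Welch-Satterthwaite df.

    Requires two or more replicates per group (single-replicate groups are
    reported descriptively upstream, not tested).  Two degenerate regimes:
    both variances zero with equal means gives t=0, p=1; both zero with
    different means is flagged degenerate with p=0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch's t-test requires >=2 replicates per group")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    var_a = float(a.var(ddof=1))
    var_b = float(b.var(ddof=1))
    if var_a == 0.0 and var_b == 0.0:
        if mean_a == mean_b:
            return WelchResult(
                mean_a, mean_b, var_a, var_b, a.size, b.size, 0.0, float(
                    a.size + b.size - 2
                ), 1.0
            )
        return WelchResult(
            mean_a,
            mean_b,
            var_a,
            var_b,
            a.size,
            b.size,
            math.copysign(math.inf, mean_a - mean_b),
            float(a.size + b.size - 2),
            0.0,
            degenerate=True,
        )
    se_a = var_a / a.size
    se_b = var_b / b.size
    t = (mean_a - mean_b) / math.sqrt(se_a + se_b)
    df = (se_a + se_b) ** 2 / (
        se_a**2 / (a.size - 1) + se_b**2 / (b.size - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(mean_a, mean_b, var_a, var_b, a.size, b.size, t, df, p)


def benjamini_hochberg(p_values: Sequence[float]) -> List[float]:
    """BH-adjusted p-values (optional; raw p-values are reported by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / (np.arange(p.size) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adjusted)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out.tolist()


def rates_frame(
    estimates: Mapping[PolymeraseClass, ErrorRateEstimate]
) -> pd.DataFrame:
    rows = []
    for pc, est in estimates.items():
        rows.append(
            {
                "group": est.group,
                "pol_class": pc.value,
                "n_replicates": est.n_replicates,
                "total_errors": sum(est.n_errors),
                "total_bases": sum(est.n_bases),
                "mean_rate": est.mean_rate,
                "sem": est.sem,
                "defined": est.defined,
            }
        )
    return pd.DataFrame(rows)


def report(
    out_dir: Union[str, Path],
    rates: Optional[Mapping[PolymeraseClass, ErrorRateEstimate]] = None,
    spectrum: Optional[SubstitutionSpectrum] = None,
    welch: Optional[Mapping[str, WelchResult]] = None,
) -> List[Path]:
    """Write machine-readable TSV/JSON reports; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if rates is not None:
        path = out_dir / "error_rates.tsv"
        rates_frame(rates).to_csv(path, sep="\t", index=False)
        written.append(path)
    if spectrum is not None:
        path = out_dir / "substitution_spectrum.tsv"
        spectrum.to_frame().to_csv(path, sep="\t", index=False)
        written.append(path)
    if welch is not None:
        path = out_dir / "welch_tests.json"
        payload = {
            label: {
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "mean_a": res.mean_a,
                "mean_b": res.mean_b,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "degenerate": res.degenerate,
            }
            for label, res in welch.items()
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written.append(path)
    return written
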