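"""Closed-form DNA:DNA duplex melting-temperature model and stringency calculus.

The melting temperature of a double-stranded DNA hybrid is modelled with the
empirical Wetmur relation

    Tm = 81.5 + 16.6*log10([Na+] / (1 + 0.7*[Na+])) + 0.41*GC - 500/N - M - 0.63*FA

where ``[Na+]`` is the monovalent sodium concentration (mol/L), ``GC`` the GC
content of the duplex (%), ``N`` its length (bp), ``M`` the percent mismatch
between probe and target, and ``FA`` the formamide concentration of the
hybridization buffer (% v/v).  Because mismatch and formamide enter linearly
(-1 °C per % mismatch, -0.63 °C per % FA), lowering the formamide
concentration by M/0.63 percentage points exactly compensates the Tm penalty
of M percent mismatch.  That trade-off is what lets a polynucleotide probe
set designed for one gene detect homologs in related taxa: hybridizing at a
relaxed FA admits correspondingly more mismatched duplexes.

The module is deliberately restricted to the printed formula: no
nearest-neighbor thermodynamics, no RNA:DNA hybrids, no oligonucleotide
corrections.  Tm values are reported unclamped; detectability decisions only
compare Tm against the hybridization temperature plus a safety margin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ProbeUnstableWarning, StringencyWarning

__all__ = [
    "DuplexParams",
    "HybridizationConditions",
    "StringencyEnvelope",
    "wetmur_tm",
    "max_mismatch",
    "recommend_fa",
    "stringency_envelope",
    "FA_COEFF_C_PER_PERCENT",
]

#: Tm depression per percent formamide in the DNA:DNA Wetmur model (°C / %FA).
FA_COEFF_C_PER_PERCENT = 0.63


@dataclass(frozen=True)
class DuplexParams:
    """Sequence-side parameters of a probe:target duplex.

    Parameters
    ----------
    gc_percent : float
        GC content of the probe in percent (0-100).
    length_bp : int
        Duplex length N in base pairs (>= 1).
    mismatch_percent : float
        Percent mismatch M between probe and target, defined as
        100 minus the percent identity of the probe-target alignment.
    """

    gc_percent: float
    length_bp: int
    mismatch_percent: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_percent <= 100.0:
            raise InvalidParameterError(f"gc_percent must be in [0, 100], got {self.gc_percent}")
        if int(self.length_bp) != self.length_bp or self.length_bp < 1:
            raise InvalidParameterError(f"length_bp must be a positive integer, got {self.length_bp}")
        if not 0.0 <= self.mismatch_percent <= 100.0:
            raise InvalidParameterError(
                f"mismatch_percent must be in [0, 100], got {self.mismatch_percent}"
            )


@dataclass(frozen=True)
class HybridizationConditions:
    """Buffer-side hybridization conditions.

    The library defaults (0.39 M Na+, 46 °C, no margin) are
    protocol-dependent placeholders for a standard geneFISH hybridization
    buffer and should be set explicitly when modelling a specific protocol.

    Parameters
    ----------
    na_molar : float
        Monovalent sodium concentration in mol/L (> 0).
    fa_percent : float
        Formamide concentration in % v/v (0-100).
    hyb_temp_c : float
        Hybridization temperature in °C.
    tm_margin_c : float
        Required excess of Tm over the hybridization temperature (°C); a
        safety margin subtracted from the mismatch budget.
    """

    na_molar: float = 0.39
    fa_percent: float = 35.0
    hyb_temp_c: float = 46.0
    tm_margin_c: float = 0.0

    def __post_init__(self) -> None:
        if not self.na_molar > 0:
            raise InvalidParameterError(f"na_molar must be > 0, got {self.na_molar}")
        if not 0.0 <= self.fa_percent <= 100.0:
            raise InvalidParameterError(f"fa_percent must be in [0, 100], got {self.fa_percent}")


def wetmur_tm(duplex: DuplexParams, cond: HybridizationConditions) -> float:
    """Melting temperature (°C) of a DNA:DNA duplex under the Wetmur model.

    Returns the formula value exactly; no clamping is applied, so the result
    may exceed 100 °C or fall below 0 °C for extreme inputs.
    """
    na = cond.na_molar
    return (
        81.5
        + 16.6 * math.log10(na / (1.0 + 0.7 * na))
        + 0.41 * duplex.gc_percent
        - 500.0 / duplex.length_bp
        - duplex.mismatch_percent
        - FA_COEFF_C_PER_PERCENT * cond.fa_percent
    )


def max_mismatch(duplex: DuplexParams, cond: HybridizationConditions) -> float:
    """Largest percent mismatch still predicted detectable at these conditions.

    Because mismatch enters the Wetmur formula with coefficient -1, the budget
    is ``Tm(M=0) - (hyb_temp_c + tm_margin_c)``, floored at 0.  A target is
    predicted detectable iff its mismatch percent is <= this value.  When even
    the perfect-match duplex melts below the hybridization temperature a
    :class:`ProbeUnstableWarning` is emitted and 0.0 returned.
    """
    tm0 = wetmur_tm(replace(duplex, mismatch_percent=0.0), cond)
    budget = tm0 - (cond.hyb_temp_c + cond.tm_margin_c)
    if budget < 0.0:
        warnings.warn(
            f"probe unstable even with perfect match: Tm(M=0) = {tm0:.2f} °C is below "
            f"hybridization temperature {cond.hyb_temp_c} °C + margin {cond.tm_margin_c} °C",
            ProbeUnstableWarning,
            stacklevel=2,
        )
        return 0.0
    return budget


def recommend_fa(
    stringent_fa: float,
    target_mismatch: float,
    rounding: str = "nearest-5",
) -> float:
    """Relaxed formamide concentration that admits ``target_mismatch`` percent mismatch.

    The FA reduction that exactly compensates the Tm penalty of M percent
    mismatch is M / 0.63, so ``FA_relaxed = stringent_fa - target_mismatch/0.63``,
    rounded per ``rounding`` and floored at 0.  Hybridization buffers are
    commonly prepared in 5 %-FA steps, hence the default rounding.

    Parameters
    ----------
    rounding : {"none", "nearest-5", "nearest-5-down"}
        ``nearest-5`` rounds to the closest multiple of 5 (half away from
        zero); ``nearest-5-down`` floors to a multiple of 5; ``none`` returns
        the raw value.
    """
    if not 0.0 <= stringent_fa <= 100.0:
        raise InvalidParameterError(f"stringent_fa must be in [0, 100], got {stringent_fa}")
    if not 0.0 <= target_mismatch <= 100.0:
        raise InvalidParameterError(f"target_mismatch must be in [0, 100], got {target_mismatch}")
    fa = stringent_fa - target_mismatch / FA_COEFF_C_PER_PERCENT
    if fa < 0.0:
        warnings.warn(
            f"a mismatch of {target_mismatch}% cannot be fully compensated by formamide "
            f"alone from a {stringent_fa}% FA design point (raw value {fa:.2f}%); "
            "returning 0% FA",
            StringencyWarning,
            stacklevel=2,
        )
    if rounding == "none":
        pass
    elif rounding == "nearest-5":
        fa = 5.0 * math.floor(fa / 5.0 + 0.5)
    elif rounding == "nearest-5-down":
        fa = 5.0 * math.floor(fa / 5.0)
    else:
        raise InvalidParameterError(f"unknown rounding mode: {rounding!r}")
    return max(fa, 0.0)


@dataclass
class StringencyEnvelope:
    """Tm grid over (formamide, mismatch) with derived stringency curves.

    ``grid`` has columns ``fa_percent, mismatch_percent, tm_c`` over the full
    cross-product; ``max_mismatch_curve`` maps each FA value to the mismatch
    budget at the envelope's hybridization temperature; ``required_fa_curve``
    maps each mismatch value to the largest FA at which it stays detectable
    (floored at 0).
    """

    duplex: DuplexParams
    cond: HybridizationConditions
    grid: pd.DataFrame
    max_mismatch_curve: pd.DataFrame = field(repr=False)
    required_fa_curve: pd.DataFrame = field(repr=False)

    def tm(self, fa: float, mismatch: float) -> float:
        row = self.grid[(self.grid.fa_percent == fa) & (self.grid.mismatch_percent == mismatch)]
        if row.empty:
            raise KeyError(f"({fa}, {mismatch}) not on the envelope grid")
        return float(row.tm_c.iloc[0])

    def to_tsv(self, path, curves_path=None) -> None:
        self.grid.to_csv(path, sep="\t", index=False)
        if curves_path is not None:
            self.max_mismatch_curve.to_csv(curves_path, sep="\t", index=False)


def stringency_envelope(
    duplex: DuplexParams,
    cond: HybridizationConditions,
    fa_values,
    mismatch_values,
) -> StringencyEnvelope:
    """Tabulate Tm across a formamide x mismatch grid and derive stringency curves."""
    fa_values = list(fa_values)
    mismatch_values = list(mismatch_values)
    if not fa_values or not mismatch_values:
        raise InvalidParameterError("fa_values and mismatch_values must be non-empty")
    rows = []
    for fa in fa_values:
        c = replace(cond, fa_percent=fa)
        for m in mismatch_values:
            d = replace(duplex, mismatch_percent=m)
            rows.append((fa, m, wetmur_tm(d, c)))
    grid = pd.DataFrame(rows, columns=["fa_percent", "mismatch_percent", "tm_c"])

    mm_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ProbeUnstableWarning)
        for fa in fa_values:
            c = replace(cond, fa_percent=fa)
            mm_rows.append((fa, max_mismatch(duplex, c)))
    mm_curve = pd.DataFrame(mm_rows, columns=["fa_percent", "max_mismatch_percent"])

    # Largest FA keeping a given mismatch detectable: Tm(M, FA) >= T_h + margin.
    fa_rows = []
    for m in mismatch_values:
        d = replace(duplex, mismatch_percent=m)
        tm_fa0 = wetmur_tm(d, replace(cond, fa_percent=0.0))
        fa_req = (tm_fa0 - cond.hyb_temp_c - cond.tm_margin_c) / FA_COEFF_C_PER_PERCENT
        fa_rows.append((m, max(fa_req, 0.0)))
    fa_curve = pd.DataFrame(fa_rows, columns=["mismatch_percent", "required_fa_percent"])

    return StringencyEnvelope(
        duplex=duplex, cond=cond, grid=grid,
        max_mismatch_curve=mm_curve, required_fa_curve=fa_curve,
    )
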