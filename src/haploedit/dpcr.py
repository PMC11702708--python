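"""Digital-PCR partition statistics for excision, inversion and allele assays.

A digital-PCR run partitions a reaction into thousands of compartments and
scores each positive/negative per fluorescence channel.  This module holds
the joint positive/negative counts (:class:`PartitionTable`) and the
estimators built on them:

* excision / inversion frequency against a 2-copy reference assay — the
  ratio of junction-positive to reference-positive partitions, optionally
  Poisson occupancy-corrected;
* 4-plex allele specificity — among junction-positive partitions that are
  positive for exactly one allele probe, the fraction carrying the target
  allele, with triple-positive (junction + both alleles) co-loading
  ambiguity excluded and reported;
* fractional abundance of one allele probe versus the other;
* target/reference expression ratios.

The default estimator everywhere is the raw positive-partition ratio; Poisson
correction (lambda = -ln(1 - k/n) per channel) is an explicit option that
removes the multi-occupancy bias that grows with loading density.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PartitionTable",
    "QuantResult",
    "DpcrError",
    "SaturationError",
    "IndeterminateError",
    "poisson_lambda",
    "excision_frequency",
    "inversion_frequency",
    "allele_specificity_4plex",
    "fractional_abundance",
    "expression_ratio",
]

AMBIGUITY_FLAG_THRESHOLD = 0.10  # paper-style QC bound on triple positives


class DpcrError(Exception):
    """Base class for digital-PCR estimation failures."""


class SaturationError(DpcrError):
    """All partitions positive: Poisson occupancy is unbounded."""


class IndeterminateError(DpcrError):
    """No informative partitions for the requested estimate."""


@dataclass(frozen=True)
class QuantResult:
    """An estimate with its confidence interval and QC flags."""

    estimate: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    method: str = "raw_ratio"
    flags: tuple[str, ...] = ()
    details: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if math.isfinite(self.ci_low) and math.isfinite(self.ci_high):
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise ValueError("confidence interval does not bracket the estimate")

    def covers(self, truth: float) -> bool:
        return self.ci_low <= truth <= self.ci_high

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "method": self.method,
            "flags": list(self.flags),
            "details": dict(self.details),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


class PartitionTable:
    """Joint positive/negative partition counts over named channels.

    ``combo_counts`` maps a tuple of booleans (one per channel, in channel
    order) to the number of partitions with that call pattern.
    """

    def __init__(self, channels: Sequence[str],
                 combo_counts: Mapping[tuple[bool, ...], int]):
        self.channels = tuple(channels)
        k = len(self.channels)
        cleaned: dict[tuple[bool, ...], int] = {}
        for combo, count in combo_counts.items():
            combo = tuple(bool(x) for x in combo)
            if len(combo) != k:
                raise ValueError(f"combo {combo} does not match {k} channels")
            if count < 0:
                raise ValueError("partition counts must be non-negative")
            if count:
                cleaned[combo] = cleaned.get(combo, 0) + int(count)
        self.combo_counts = cleaned
        self.n_total = sum(cleaned.values())
        if self.n_total == 0:
            raise ValueError("partition table is empty")

    @classmethod
    def from_boolean_matrix(cls, channels: Sequence[str],
                            matrix: np.ndarray) -> "PartitionTable":
        """Build from an (n_partitions, n_channels) boolean call matrix."""
        matrix = np.asarray(matrix, dtype=bool)
        combos, counts = np.unique(matrix, axis=0, return_counts=True)
        return cls(channels, {tuple(row): int(c) for row, c in zip(combos, counts)})

    @classmethod
    def from_two_channel_totals(cls, channels: Sequence[str], pos_a: int,
                                pos_b: int, n_total: int) -> "PartitionTable":
        """2-plex table from marginal positive totals, assuming independent
        channel co-occurrence (exact joint counts are not needed for the
        marginal raw/Poisson estimators)."""
        if len(channels) != 2:
            raise ValueError("expected exactly two channel names")
        if pos_a > n_total or pos_b > n_total:
            raise ValueError("positives exceed total partitions")
        pa, pb = pos_a / n_total, pos_b / n_total
        grid = {}
        for a in (False, True):
            for b in (False, True):
                frac = (pa if a else 1 - pa) * (pb if b else 1 - pb)
                grid[(a, b)] = int(round(frac * n_total))
        drift = n_total - sum(grid.values())
        grid[(False, False)] += drift
        return cls(channels, grid)

    # -- queries -----------------------------------------------------------

    def _index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"no channel {channel!r}; have {self.channels}") from None

    def count(self, positive: Sequence[str] = (),
              negative: Sequence[str] = ()) -> int:
        """Partitions positive for all of ``positive`` and negative for all
        of ``negative``; unmentioned channels are unconstrained."""
        pos_idx = [self._index(c) for c in positive]
        neg_idx = [self._index(c) for c in negative]
        total = 0
        for combo, n in self.combo_counts.items():
            if all(combo[i] for i in pos_idx) and not any(combo[i] for i in neg_idx):
                total += n
        return total

    def positives(self, channel: str) -> int:
        return self.count(positive=[channel])

    def marginal(self, channels: Sequence[str]) -> "PartitionTable":
        """Collapse to a sub-table over the named channels."""
        idx = [self._index(c) for c in channels]
        out: dict[tuple[bool, ...], int] = {}
        for combo, n in self.combo_counts.items():
            key = tuple(combo[i] for i in idx)
            out[key] = out.get(key, 0) + n
        return PartitionTable(channels, out)

    def scale(self, factor: int) -> "PartitionTable":
        return PartitionTable(self.channels,
                              {c: n * factor for c, n in self.combo_counts.items()})

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {**{c: int(flag) for c, flag in zip(self.channels, combo)}, "count": n}
            for combo, n in sorted(self.combo_counts.items())
        ]
        return pd.DataFrame(rows, columns=[*self.channels, "count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PartitionTable":
        df = pd.read_csv(path, sep="\t")
        if "count" not in df.columns:
            raise ValueError("partition TSV needs a 'count' column")
        channels = [c for c in df.columns if c != "count"]
        combos = {
            tuple(bool(row[c]) for c in channels): int(row["count"])
            for _, row in df.iterrows()
        }
        return cls(channels, combos)

    def __repr__(self) -> str:
        return (f"PartitionTable(channels={self.channels}, "
                f"n_total={self.n_total}, n_combos={len(self.combo_counts)})")


def poisson_lambda(k_pos: int, n: int) -> float:
    """Mean molecules per partition from the positive fraction.

    Standard digital-PCR occupancy inversion: lambda = -ln(1 - k/n).
    """
    if n <= 0:
        raise ValueError("total partition count must be positive")
    if not 0 <= k_pos <= n:
        raise ValueError(f"positive count {k_pos} outside [0, {n}]")
    if k_pos == n:
        raise SaturationError("every partition positive: occupancy is unbounded")
    return -math.log1p(-k_pos / n)


def _lambda_log_var(k: int, n: int) -> float:
    """Delta-method variance of ln(lambda-hat) for k positives of n."""
    p = k / n
    lam = poisson_lambda(k, n)
    if k == 0:
        return math.inf
    return p / (n * (1.0 - p) * lam * lam)


def _ratio_result(k_num: int, k_den: int, n: int, method: str,
                  ci_level: float, flags: tuple[str, ...] = (),
                  details: Mapping[str, float] | None = None) -> QuantResult:
    """Shared machinery: ratio of two positive-partition counts with a
    delta-method CI on the log scale (raw) or on log-lambda (corrected)."""
    z = stats.norm.ppf(0.5 + ci_level / 2)
    details = dict(details or {})
    details.update({"k_num": k_num, "k_den": k_den, "n": n})
    if method == "raw_ratio":
        est = k_num / k_den
        if k_num == 0:
            lo, hi = 0.0, 0.0 if n == 0 else 3.0 / k_den  # rule-of-three upper bound
            return QuantResult(est, lo, max(hi, est), ci_level, method, flags, details)
        p1, p2 = k_num / n, k_den / n
        log_var = (1 - p1) / (n * p1) + (1 - p2) / (n * p2)
        half = z * math.sqrt(log_var)
        return QuantResult(est, est * math.exp(-half), est * math.exp(half),
                           ci_level, method, flags, details)
    if method == "poisson_corrected":
        lam_num = poisson_lambda(k_num, n)
        lam_den = poisson_lambda(k_den, n)
        if lam_den == 0:
            raise IndeterminateError("reference occupancy is zero")
        est = lam_num / lam_den
        details.update({"lambda_num": lam_num, "lambda_den": lam_den})
        if k_num == 0:
            return QuantResult(0.0, 0.0, poisson_lambda(3, n) / lam_den,
                               ci_level, method, flags, details)
        log_var = _lambda_log_var(k_num, n) + _lambda_log_var(k_den, n)
        half = z * math.sqrt(log_var)
        return QuantResult(est, est * math.exp(-half), est * math.exp(half),
                           ci_level, method, flags, details)
    raise ValueError(f"unknown method {method!r}")


def _junction_frequency(table: PartitionTable, junction_channel: str,
                        reference_channel: str, method: str,
                        ci_level: float) -> QuantResult:
    k_j = table.positives(junction_channel)
    k_r = table.positives(reference_channel)
    if k_r == 0:
        raise IndeterminateError("no reference-positive partitions")
    return _ratio_result(k_j, k_r, table.n_total, method, ci_level)


def excision_frequency(table: PartitionTable, method: str = "raw_ratio",
                       ci_level: float = 0.95,
                       excision_channel: str = "excision",
                       reference_channel: str = "reference") -> QuantResult:
    """Fraction of gene alleles excised.

    Raw: (junction-positive partitions) / (reference-positive partitions).
    Both the reference assay and the gene contribute two copies per genome,
    so the ratio estimates the excised fraction of all gene copies.  The
    Poisson-corrected variant uses the occupancy ratio instead and is
    unbiased at any loading density.
    """
    return _junction_frequency(table, excision_channel, reference_channel,
                               method, ci_level)


def inversion_frequency(table: PartitionTable, method: str = "raw_ratio",
                        ci_level: float = 0.95,
                        inversion_channel: str = "inversion",
                        reference_channel: str = "reference") -> QuantResult:
    """Fraction of gene alleles carrying the inversion junction; same
    mathematics as :func:`excision_frequency` on the inversion channel."""
    return _junction_frequency(table, inversion_channel, reference_channel,
                               method, ci_level)


def allele_specificity_4plex(table: PartitionTable, ci_level: float = 0.95,
                             excision_channel: str = "excision",
                             target_channel: str = "target_allele",
                             other_channel: str = "other_allele",
                             ambiguity_threshold: float = AMBIGUITY_FLAG_THRESHOLD,
                             ) -> QuantResult:
    """Fraction of excision events on the target allele, from the 4-plex.

    specificity = n(junction & target & !other) /
                  [n(junction & target & !other) + n(junction & other & !target)]

    Triple-positive partitions (junction plus both allele probes) are
    co-loading ambiguities and are excluded; their share of all
    junction-positive partitions is reported and flagged when it reaches
    ``ambiguity_threshold``.  Junction-positive partitions with no allele
    signal carry no allele information and are likewise excluded and
    reported.  CI: Wilson interval on the qualifying double-positives.
    """
    n_target = table.count(positive=[excision_channel, target_channel],
                           negative=[other_channel])
    n_other = table.count(positive=[excision_channel, other_channel],
                          negative=[target_channel])
    n_triple = table.count(positive=[excision_channel, target_channel, other_channel])
    n_silent = table.count(positive=[excision_channel],
                           negative=[target_channel, other_channel])
    n_exc = n_target + n_other + n_triple + n_silent
    if n_target + n_other == 0:
        raise IndeterminateError(
            "no junction-positive partitions with exactly one allele signal")
    est = n_target / (n_target + n_other)
    lo, hi = proportion_confint(n_target, n_target + n_other,
                                alpha=1 - ci_level, method="wilson")
    lo, hi = min(float(lo), est), max(float(hi), est)  # Wilson can exclude 0/1 MLEs
    ambiguity = n_triple / n_exc if n_exc else 0.0
    flags = ("high_ambiguity",) if ambiguity >= ambiguity_threshold else ()
    details = {
        "n_target_only": n_target,
        "n_other_only": n_other,
        "n_triple_positive": n_triple,
        "n_no_allele_signal": n_silent,
        "triple_positive_fraction": ambiguity,
        "no_allele_fraction": n_silent / n_exc if n_exc else 0.0,
    }
    return QuantResult(est, float(lo), float(hi), ci_level, "raw_ratio",
                       flags, details)


def fractional_abundance(pos_a: int, pos_b: int, n: int,
                         method: str = "raw_ratio",
                         ci_level: float = 0.95) -> QuantResult:
    """Share of probe A among both probes: pos_a / (pos_a + pos_b), or the
    same on Poisson occupancies.  0.5 is the unedited-heterozygote baseline."""
    if pos_a > n or pos_b > n:
        raise ValueError("positives exceed total partitions")
    if pos_a + pos_b == 0:
        raise IndeterminateError("no positive partitions on either probe")
    if method == "raw_ratio":
        est = pos_a / (pos_a + pos_b)
        lo, hi = proportion_confint(pos_a, pos_a + pos_b, alpha=1 - ci_level,
                                    method="wilson")
        lo, hi = min(float(lo), est), max(float(hi), est)
        return QuantResult(est, lo, hi, ci_level, method)
    if method == "poisson_corrected":
        lam_a = poisson_lambda(pos_a, n)
        lam_b = poisson_lambda(pos_b, n)
        est = lam_a / (lam_a + lam_b)
        # delta method on the log odds lam_a/lam_b
        if pos_a == 0 or pos_b == 0:
            lo, hi = (0.0, est) if pos_a == 0 else (est, 1.0)
            return QuantResult(est, min(lo, est), max(hi, est), ci_level, method)
        z = stats.norm.ppf(0.5 + ci_level / 2)
        half = z * math.sqrt(_lambda_log_var(pos_a, n) + _lambda_log_var(pos_b, n))
        odds = lam_a / lam_b
        lo = odds * math.exp(-half) / (1 + odds * math.exp(-half))
        hi = odds * math.exp(half) / (1 + odds * math.exp(half))
        return QuantResult(est, lo, hi, ci_level, method)
    raise ValueError(f"unknown method {method!r}")


def expression_ratio(target_pos: int, ref_pos: int, n: int,
                     method: str = "raw_ratio",
                     ci_level: float = 0.95) -> QuantResult:
    """Target-positive over reference-positive partition ratio (e.g. a gene
    expression assay normalised to a housekeeping channel).  Normalising to a
    control sample is a further division left to the caller."""
    if target_pos > n or ref_pos > n:
        raise ValueError("positives exceed total partitions")
    if ref_pos == 0:
        raise IndeterminateError("no reference-positive partitions")
    return _ratio_result(target_pos, ref_pos, n, method, ci_level)
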