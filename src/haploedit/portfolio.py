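"""Greedy reagent-portfolio selection and patient-coverage curves.

How many distinct Cas/gRNA reagents does it take to treat a given share of
patients?  Three strategies are compared:

* ``snp_pair`` — dual allele-specific guides at a flanking SNP pair; a
  patient is treatable when heterozygous at both SNPs (maximum-coverage
  greedy over the pairs' double-heterozygote sets);
* ``anchored_single`` — one constant biallelic guide (shared by every
  therapy) plus one allele-specific guide at a single flanking SNP; a
  patient is treatable when heterozygous at that SNP;
* ``mutation_specific`` — the baseline of one reagent per distinct disease
  mutation, idealised as equal-frequency mutations so k reagents cover
  k/n_mutations of patients.

Coverage is plotted against the number of unique reagents, deduplicating
SNPs shared between selected pairs (per_snp convention) or counting each
targetable allele separately (per_allele).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .pairs import CandidateVariants, SnpPair
from .panel import PhasedPanel

__all__ = [
    "Therapy",
    "Portfolio",
    "CountingConvention",
    "StopRule",
    "greedy_pair_portfolio",
    "greedy_anchor_portfolio",
    "mutation_baseline_curve",
    "reagent_count",
    "coverage_curve",
]


@dataclass(frozen=True)
class CountingConvention:
    """How selections translate into unique molecular reagents.

    per_snp: one optimised Cas/gRNA per SNP site (a SNP shared by two pairs
    is counted once).  per_allele: one per (SNP site, targeted allele), both
    alleles counted as targetable.  ``anchor_reagents`` adds the constant
    biallelic guide (1 in anchor mode, else 0).
    """

    mode: Literal["per_snp", "per_allele"] = "per_snp"
    anchor_reagents: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("per_snp", "per_allele"):
            raise ValueError(f"unknown counting mode {self.mode!r}")


@dataclass(frozen=True)
class StopRule:
    """Stop when coverage reaches ``target_coverage``, after ``max_items``
    selections, or at exhaustion (no candidate adds coverage)."""

    target_coverage: float | None = None
    max_items: int | None = None


@dataclass(frozen=True)
class Therapy:
    kind: Literal["snp_pair", "anchored_single", "mutation_specific"]
    members: tuple[int, ...]  # SNP variant indices (2, 1, or 0 for mutation)
    covered: frozenset[int]
    span_bp: int | None = None
    label: str = ""


@dataclass
class Portfolio:
    """An ordered greedy selection with per-step marginal gains and
    cumulative coverage."""

    n_samples: int
    selections: list[Therapy]
    marginal_gains: list[int]
    cumulative_covered: list[frozenset[int]]
    stop_reason: str
    anchor_reagents: int = 0

    @property
    def n_steps(self) -> int:
        return len(self.selections)

    @property
    def coverage_fractions(self) -> list[float]:
        return [len(c) / self.n_samples for c in self.cumulative_covered]

    @property
    def final_coverage(self) -> float:
        return self.coverage_fractions[-1] if self.selections else 0.0

    def summary_frame(self, convention: CountingConvention | None = None) -> pd.DataFrame:
        conv = convention or CountingConvention(anchor_reagents=self.anchor_reagents)
        reagents = reagent_count(self, conv)
        return pd.DataFrame(
            {
                "step": np.arange(1, self.n_steps + 1),
                "therapy": [t.label or "+".join(map(str, t.members))
                            for t in self.selections],
                "marginal_gain": self.marginal_gains,
                "reagents": reagents,
                "coverage": self.coverage_fractions,
            }
        )

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "stop_reason": self.stop_reason,
            "anchor_reagents": self.anchor_reagents,
            "selections": [
                {
                    "kind": t.kind,
                    "members": list(t.members),
                    "label": t.label,
                    "marginal_gain": g,
                    "cumulative_coverage": len(c) / self.n_samples,
                }
                for t, g, c in zip(self.selections, self.marginal_gains,
                                   self.cumulative_covered)
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _greedy(candidates: list[Therapy], keys: list[tuple], n_samples: int,
            stop: StopRule, per_reagent: bool = False) -> Portfolio:
    """Core greedy maximum-coverage loop.

    ``keys`` give the deterministic tie-break for equal marginal gains
    (smaller key preferred).  With ``per_reagent`` the objective is marginal
    gain divided by the number of previously unused SNP sites the candidate
    introduces (coverage per new reagent).
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    covered: set[int] = set()
    used_sites: set[int] = set()
    remaining = list(range(len(candidates)))
    selections: list[Therapy] = []
    gains: list[int] = []
    cumulative: list[frozenset[int]] = []
    stop_reason = "exhausted"
    while remaining:
        best_idx, best_score, best_gain = None, None, 0
        for idx in remaining:
            cand = candidates[idx]
            gain = len(cand.covered - covered)
            if gain == 0:
                continue
            if per_reagent:
                new_sites = max(len(set(cand.members) - used_sites), 1)
                objective = gain / new_sites
            else:
                objective = gain
            score = (-objective, keys[idx])
            if best_score is None or score < best_score:
                best_idx, best_score, best_gain = idx, score, gain
        if best_idx is None:
            break  # nothing adds coverage
        cand = candidates[best_idx]
        covered |= cand.covered
        used_sites |= set(cand.members)
        remaining.remove(best_idx)
        selections.append(cand)
        gains.append(best_gain)
        cumulative.append(frozenset(covered))
        if stop.target_coverage is not None and len(covered) / n_samples >= stop.target_coverage:
            stop_reason = "target_reached"
            break
        if stop.max_items is not None and len(selections) >= stop.max_items:
            stop_reason = "max_items"
            break
    if not per_reagent:
        # submodularity can be broken by the per-reagent objective; plain
        # greedy gains are monotone by construction and asserted here
        gains_ok = all(a >= b for a, b in zip(gains, gains[1:]))
        assert gains_ok, "greedy marginal gains must be non-increasing"
    return Portfolio(n_samples=n_samples, selections=selections,
                     marginal_gains=gains, cumulative_covered=cumulative,
                     stop_reason=stop_reason)


def greedy_pair_portfolio(pairs: Sequence[SnpPair], n_samples: int,
                          stop: StopRule = StopRule(),
                          labels: Sequence[str] | None = None,
                          per_reagent: bool = False) -> Portfolio:
    """Greedy maximum coverage over SNP pairs.

    Each step selects the pair heterozygous-at-both-SNPs in the largest
    number of not-yet-covered individuals.  Ties prefer the smaller excision
    span, then the lexicographically smallest (left pos, right pos) — a
    deterministic rule independent of input order.
    """
    cands = []
    keys = []
    for i, p in enumerate(pairs):
        label = labels[i] if labels else f"pair({p.left},{p.right})"
        cands.append(Therapy(kind="snp_pair", members=(p.left, p.right),
                             covered=p.covered, span_bp=len(p.span), label=label))
        keys.append((len(p.span), p.span.start, p.span.end))
    return _greedy(cands, keys, n_samples, stop, per_reagent=per_reagent)


def greedy_anchor_portfolio(cands: CandidateVariants, panel: PhasedPanel,
                            stop: StopRule = StopRule()) -> Portfolio:
    """Greedy over single flanking SNPs paired with the constant biallelic
    anchor guide: a sample is covered when heterozygous at the SNP.  The
    anchor contributes one reagent in total, recorded on the portfolio."""
    het = panel.het_mask()
    singles = []
    keys = []
    for j in sorted(set(cands.left) | set(cands.right)):
        covered = frozenset(np.flatnonzero(het[:, j]).tolist())
        singles.append(Therapy(kind="anchored_single", members=(j,),
                               covered=covered, label=panel.variants[j].id))
        keys.append((panel.variants[j].pos,))
    pf = _greedy(singles, keys, panel.n_samples, stop)
    pf.anchor_reagents = 1
    return pf


def mutation_baseline_curve(n_mutations: int) -> list[tuple[int, float]]:
    """Coverage of the mutation-targeted baseline: with n equal-frequency
    mutations, k mutation-specific reagents treat k/n of patients."""
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    return [(k, k / n_mutations) for k in range(n_mutations + 1)]


def reagent_count(portfolio: Portfolio,
                  convention: CountingConvention) -> list[int]:
    """Cumulative unique-reagent count after each greedy step."""
    counts = []
    sites: set[int] = set()
    for t in portfolio.selections:
        if t.kind == "mutation_specific":
            counts.append(len(counts) + 1)
            continue
        sites |= set(t.members)
        per_site = 2 if convention.mode == "per_allele" else 1
        counts.append(per_site * len(sites) + convention.anchor_reagents)
    return counts


def coverage_curve(portfolio: Portfolio,
                   convention: CountingConvention) -> list[tuple[int, float]]:
    """(unique reagents, cumulative coverage fraction) after each step; an
    empty portfolio yields the single point (anchor_reagents, 0.0)."""
    if not portfolio.selections:
        return [(convention.anchor_reagents, 0.0)]
    reagents = reagent_count(portfolio, convention)
    return list(zip(reagents, portfolio.coverage_fractions))


def plot_coverage_curves(curves: dict[str, list[tuple[int, float]]], ax=None):
    """Step plot of coverage (%) against unique reagent count, one line per
    strategy.  Returns the matplotlib axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, pts in curves.items():
        xs = [0] + [x for x, _ in pts]
        ys = [0.0] + [100 * y for _, y in pts]
        ax.step(xs, ys, where="post", label=label)
    ax.set_xlabel("unique Cas/gRNA reagents")
    ax.set_ylabel("patients treatable (%)")
    ax.legend()
    return ax
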