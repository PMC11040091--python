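"""Validation statistics: contingency tables, sensitivity/specificity, and
Sison-Glaz simultaneous confidence intervals for multinomial proportions.

The Sison-Glaz procedure finds the integer half-width ``c`` with
``nu(c) < 1 - alpha <= nu(c + 1)``, where ``nu(c)`` approximates the
multinomial probability that every category count stays within ``c`` of its
observed value.  The approximation is the product of doubly-truncated-Poisson
cell probabilities times a second-order Edgeworth density correction (terms
in the skewness gamma_1 and excess kurtosis gamma_2 of the truncated sum).
The reported intervals are ``[p_i - c/n, p_i + c/n + 2*gamma/n]`` truncated
to [0, 1], with ``gamma`` interpolating between ``nu(c)`` and ``nu(c + 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import pdtr

from .model import LABELS, ContingencyTable, SimultaneousCI


def _poisson_cdf(k: float, lam: float) -> float:
    """P(Poisson(lam) <= k) for integer k >= 0 (fast special-function path)."""
    return float(pdtr(k, lam))


def build_contingency(
    expert_labels: Mapping[str, str], procedure_labels: Mapping[str, str]
) -> ContingencyTable:
    """3x3 expert-vs-procedure table over {fortified, non_fortified, ineligible}.

    Both mappings are food_id -> label and must cover the same foods.
    """
    if set(expert_labels) != set(procedure_labels):
        unpaired = set(expert_labels) ^ set(procedure_labels)
        raise ValueError(f"unpaired food ids: {sorted(unpaired)[:5]} ...")
    index = {label: i for i, label in enumerate(LABELS)}
    counts = [[0, 0, 0] for _ in LABELS]
    for food_id, expert in expert_labels.items():
        counts[index[expert]][index[procedure_labels[food_id]]] += 1
    return ContingencyTable(counts=tuple(tuple(row) for row in counts))


def _truncated_poisson_moments(c: int, lam: float) -> tuple[float, float, float, float, float]:
    """First four central moments and the normalizing mass of a Poisson(lam)
    truncated to [max(lam - c, 0), lam + c], via factorial moments."""
    a = lam + c
    b = max(lam - c, 0.0)
    den = _poisson_cdf(a, lam) - (_poisson_cdf(b - 1, lam) if b >= 1 else 0.0)
    mu = []
    for r in range(1, 5):
        pois_a = _poisson_cdf(a, lam) - (_poisson_cdf(a - r, lam) if a - r >= 0 else 0.0)
        if b - r - 1 >= 0:
            pois_b = _poisson_cdf(b - 1, lam) - _poisson_cdf(b - r - 1, lam)
        elif b - 1 >= 0:
            pois_b = _poisson_cdf(b - 1, lam)
        else:
            pois_b = 0.0
        mu.append(lam**r * (1.0 - (pois_a - pois_b) / den))
    m1 = mu[0]
    m2 = mu[1] + mu[0] - mu[0] ** 2
    m3 = mu[2] + mu[1] * (3 - 3 * mu[0]) + (mu[0] - 3 * mu[0] ** 2 + 2 * mu[0] ** 3)
    m4 = (
        mu[3]
        + mu[2] * (6 - 4 * mu[0])
        + mu[1] * (7 - 12 * mu[0] + 6 * mu[0] ** 2)
        + mu[0]
        - 4 * mu[0] ** 2
        + 6 * mu[0] ** 3
        - 3 * mu[0] ** 4
    )
    return m1, m2, m3, m4, den


def sison_glaz_nu(c: int, counts: Sequence[int]) -> float:
    """Edgeworth approximation of P(|N_i - n_i| <= c for all i)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    moments = [_truncated_poisson_moments(c, x) for x in counts]
    s1 = sum(m[0] for m in moments)
    s2 = sum(m[1] for m in moments)
    s3 = sum(m[2] for m in moments)
    s4 = sum(m[3] - 3 * m[1] ** 2 for m in moments)  # excess-kurtosis numerator
    if s2 <= 0:
        return math.nan
    prob_n = 1.0 / (_poisson_cdf(n, n) - _poisson_cdf(n - 1, n))
    z = (n - s1) / math.sqrt(s2)
    g1 = s3 / s2**1.5
    g2 = s4 / s2**2
    poly = 1.0 + g1 * (z**3 - 3 * z) / 6.0 + g2 * (z**4 - 6 * z**2 + 3) / 24.0
    density = poly * math.exp(-(z**2) / 2.0) / math.sqrt(2.0 * math.pi)
    prob_cells = math.prod(m[4] for m in moments)
    return prob_n * prob_cells * density / math.sqrt(s2)


def row_proportions_with_ci(
    row_counts: Sequence[int], alpha: float = 0.05
) -> list[SimultaneousCI]:
    """Simultaneous (1 - alpha) intervals for one multinomial count vector.

    The search walks c upward from 1 with the previous coverage initialized
    to 0, takes the first c whose approximate coverage exceeds 1 - alpha,
    interpolates gamma there, and uses half-width c - 1.  Degenerate vectors
    (a single nonzero cell) resolve on the first step and yield valid,
    possibly zero-width, intervals.
    """
    counts = np.asarray(row_counts, dtype=float)
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite and non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("row total must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    p = counts / n
    nu_prev = 0.0
    c_found = None
    nu_found = None
    for c in range(1, int(n) + 1):
        v = sison_glaz_nu(c, counts)
        if v > 1.0 - alpha:
            c_found, nu_found = c, v
            break
        nu_prev = v
    if c_found is None:  # coverage never reached; widest possible interval
        c_found, nu_found = int(n), 1.0
    gamma = (1.0 - alpha - nu_prev) / (nu_found - nu_prev)
    half = (c_found - 1) / n
    out = []
    for i, pi in enumerate(p):
        lower = max(0.0, pi - half)
        upper = min(1.0, pi + half + 2.0 * gamma / n)
        out.append(
            SimultaneousCI(
                category=i,
                point=float(pi),
                lower=float(lower),
                upper=float(min(upper, 1.0)),
                confidence_level=1.0 - alpha,
            )
        )
    return out


def sensitivity(table: ContingencyTable, include_ineligible: bool = False) -> float:
    """True-positive rate of the procedure against the expert labels.

    By default foods the procedure deemed ineligible are excluded from the
    denominator, i.e. TP / (TP + FN over the fortified/non-fortified calls).
    """
    tp = table.cell("fortified", "fortified")
    fn = table.cell("fortified", "non_fortified")
    denom = tp + fn
    if include_ineligible:
        denom += table.cell("fortified", "ineligible")
    if denom == 0:
        raise ValueError("no expert-fortified foods with a procedure call")
    return tp / denom


def specificity(table: ContingencyTable, include_ineligible: bool = True) -> float:
    """True-negative rate; procedure-ineligible foods count in the denominator
    by default (they are missed non-fortified calls)."""
    tn = table.cell("non_fortified", "non_fortified")
    fp = table.cell("non_fortified", "fortified")
    denom = tn + fp
    if include_ineligible:
        denom += table.cell("non_fortified", "ineligible")
    if denom == 0:
        raise ValueError("no expert-non-fortified foods")
    return tn / denom


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention used for report percentages."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


@dataclass(frozen=True)
class ValidationReport:
    """Per-nutrient expert-vs-procedure comparison in Table-style layout."""

    tables: Mapping[str, ContingencyTable]
    alpha: float = 0.05

    def row_cis(self, nutrient: str, expert_label: str) -> list[SimultaneousCI]:
        return row_proportions_with_ci(
            self.tables[nutrient].row(expert_label), self.alpha
        )

    def sensitivity(self, nutrient: str) -> float:
        return sensitivity(self.tables[nutrient])

    def specificity(self, nutrient: str) -> float:
        return specificity(self.tables[nutrient])

    def to_frame(self) -> pd.DataFrame:
        """Rows = (nutrient, expert class); columns = procedure classes as
        "n (pct%) CI: lo-hi%", plus sensitivity/specificity columns."""
        rows = []
        for nutrient, table in self.tables.items():
            for expert_label in LABELS:
                row_counts = table.row(expert_label)
                total = sum(row_counts)
                entry = {
                    "nutrient": nutrient,
                    "expert_class": expert_label,
                    "total": total,
                }
                if total > 0:
                    cis = row_proportions_with_ci(row_counts, self.alpha)
                else:
                    cis = None
                for j, proc_label in enumerate(LABELS):
                    if cis is None:
                        entry[f"procedure_{proc_label}"] = "0"
                        continue
                    ci = cis[j]
                    entry[f"procedure_{proc_label}"] = (
                        f"{row_counts[j]} ({round_half_away(100 * ci.point):.1f}%) "
                        f"CI: {round_half_away(100 * ci.lower):.1f}-"
                        f"{round_half_away(100 * ci.upper):.1f}%"
                    )
                rows.append(entry)
        frame = pd.DataFrame(rows)
        frame["sensitivity"] = [
            round_half_away(100 * sensitivity(self.tables[r["nutrient"]]))
            for _, r in frame.iterrows()
        ]
        frame["specificity"] = [
            round_half_away(100 * specificity(self.tables[r["nutrient"]]))
            for _, r in frame.iterrows()
        ]
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def validation_report(
    expert: Mapping[str, Mapping[str, str]],
    procedure: Mapping[str, Mapping[str, str]],
    alpha: float = 0.05,
) -> ValidationReport:
    """Build a report from per-nutrient {food_id: label} mappings."""
    tables = {
        nutrient: build_contingency(expert[nutrient], procedure[nutrient])
        for nutrient in expert
    }
    return ValidationReport(tables=tables, alpha=alpha)
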