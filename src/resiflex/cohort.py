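"""Clinical cohort analysis: contingency tables, Fisher tests, rankers.

A cohort is a table with 24 categorical attributes (six age-threshold
booleans, sex, smoking, six site-of-metastasis booleans, number of
metastatic sites, initial EGFR mutation type, TKI/chemotherapy line counts
and usage flags) plus the binary acquired-T790M outcome.  This module
validates cohorts, builds attribute-by-outcome contingency tables, reports
proportions with exact fractions plus round-half-up single-decimal
percentages, runs the two-sided Fisher's exact test (point-probability
rule) on 2x2 tables, and ranks attributes by their association with the
outcome using reimplementations of six standard categorical measures
(chi-squared, information gain, symmetrical uncertainty, Pearson
correlation on indicator encodings, ReliefF, and information gain behind
the validation filter).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortValidationError, ResiflexError

#: the 24 ranked attributes, in schema order
ATTRIBUTES: Tuple[str, ...] = (
    "age_55", "age_60", "age_65", "age_70", "age_75", "age_80",
    "sex", "smoking",
    "lung_met", "pleural_met", "brain_met", "liver_met", "bone_met",
    "distant_ln_met",
    "number_sites_met", "initial_egfr_mutation",
    "number_lines_tki", "number_lines_chemo",
    "first_tki", "second_tki_used", "third_tki_used",
    "first_chemo_used", "second_chemo_used", "third_chemo_used",
)

OUTCOME = "t790m"

MUTATION_LEVELS = ("exon19_LRE_delE746_A750", "exon19_LRE_other",
                   "exon19_nonLRE", "L858R")
SEX_LEVELS = ("male", "female")
SMOKING_LEVELS = ("never", "chronic", "ex")
TKI_LEVELS = ("gefitinib", "erlotinib", "afatinib")

_BOOL_ATTRS = ("age_55", "age_60", "age_65", "age_70", "age_75", "age_80",
               "lung_met", "pleural_met", "brain_met", "liver_met",
               "bone_met", "distant_ln_met", "second_tki_used",
               "third_tki_used", "first_chemo_used", "second_chemo_used",
               "third_chemo_used", OUTCOME)

_LEVELED = {"sex": SEX_LEVELS, "smoking": SMOKING_LEVELS,
            "initial_egfr_mutation": MUTATION_LEVELS, "first_tki": TKI_LEVELS}

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _as_bool(v, where: str) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"{where}: {v!r} is not a boolean")


def validate_cohort(df: pd.DataFrame) -> List[str]:
    """Return a list of per-row validation messages (empty = valid)."""
    errors: List[str] = []
    missing = [c for c in ATTRIBUTES + (OUTCOME,) if c not in df.columns]
    if missing:
        return [f"missing column(s): {', '.join(missing)}"]
    if len(df) == 0:
        return ["cohort is empty"]
    for idx, row in df.iterrows():
        where = f"row {idx}"
        try:
            ages = [_as_bool(row[f"age_{t}"], f"{where} age_{t}")
                    for t in (55, 60, 65, 70, 75, 80)]
            for a_lo, a_hi, t_hi in zip(ages, ages[1:], (60, 65, 70, 75, 80)):
                if a_hi and not a_lo:
                    errors.append(
                        f"{where}: age_{t_hi} true but a lower age threshold "
                        "is false (age thresholds must be monotone)")
                    break
            for col in _BOOL_ATTRS:
                _as_bool(row[col], f"{where} {col}")
        except ValueError as exc:
            errors.append(str(exc))
            continue
        for col, levels in _LEVELED.items():
            if str(row[col]) not in levels:
                errors.append(f"{where}, column {col}: unknown level "
                              f"{row[col]!r} (expected one of {levels})")
        try:
            if int(row["number_sites_met"]) < 1:
                errors.append(f"{where}: number_sites_met must be >= 1")
        except (TypeError, ValueError):
            errors.append(f"{where}: number_sites_met is not an integer")
        for col, lo in (("number_lines_tki", 1), ("number_lines_chemo", 0)):
            try:
                if int(row[col]) < lo:
                    errors.append(f"{where}: {col} must be >= {lo}")
            except (TypeError, ValueError):
                errors.append(f"{where}: {col} is not an integer")
    return errors


def coerce_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize column dtypes (booleans, ints, categorical strings)."""
    out = df.copy()
    for col in _BOOL_ATTRS:
        out[col] = [_as_bool(v, col) for v in out[col]]
    for col in ("number_sites_met", "number_lines_tki", "number_lines_chemo"):
        out[col] = out[col].astype(np.int64)
    for col in _LEVELED:
        out[col] = out[col].astype(str)
    return out


def load_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises with all per-row messages."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CohortValidationError(["cohort file is empty"]) from None
    errors = validate_cohort(df)
    if errors:
        raise CohortValidationError(errors)
    return coerce_cohort(df)


# ---------------------------------------------------------------------------
# contingency tables and proportions

@dataclass
class ContingencyTable:
    """r x c nonnegative integer counts with row/column labels."""

    counts: np.ndarray
    row_labels: Tuple
    col_labels: Tuple

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ResiflexError("contingency counts must be 2-dimensional")
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise ResiflexError("counts must be >= 0 with a positive total")
        self.row_labels = tuple(self.row_labels)
        self.col_labels = tuple(self.col_labels)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ResiflexError("labels do not match count matrix shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


def _level_order(col: str, values) -> list:
    if col in _LEVELED:
        present = set(str(v) for v in values)
        return [l for l in _LEVELED[col] if l in present]
    uniq = sorted(set(values), key=lambda v: (str(type(v)), v))
    if set(uniq) <= {False, True}:
        # positive level first: bone+/outcome+ lead, matching clinical tables
        return [l for l in (True, False) if l in uniq]
    return uniq


def build_contingency(cohort: pd.DataFrame, attribute: str,
                      outcome: str = OUTCOME) -> ContingencyTable:
    """Counts of attribute level x outcome level, deterministic label order.

    Boolean columns order False, True; leveled categoricals follow their
    schema order; anything else sorts ascending.
    """
    if attribute not in cohort.columns:
        raise ResiflexError(f"unknown attribute {attribute!r}")
    rows = _level_order(attribute, cohort[attribute])
    cols = _level_order(outcome, cohort[outcome])
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for i, rv in enumerate(rows):
        sel = cohort[attribute] == rv
        for j, cv in enumerate(cols):
            counts[i, j] = int((sel & (cohort[outcome] == cv)).sum())
    return ContingencyTable(counts, rows, cols)


@dataclass(frozen=True)
class Proportion:
    """k/n with the printed-style round-half-up single-decimal percentage."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> Optional[Fraction]:
        if self.denominator == 0:
            return None
        return Fraction(self.numerator, self.denominator)

    @property
    def percent(self) -> Optional[float]:
        """Exact percentage (float); None for an empty denominator."""
        if self.denominator == 0:
            return None
        return 100.0 * self.numerator / self.denominator

    @property
    def percent_rounded(self) -> Optional[float]:
        """Percentage rounded half-up to 1 decimal (reporting convention);
        None (printed blank) for an empty denominator."""
        if self.denominator == 0:
            return None
        exact = Decimal(100 * self.numerator) / Decimal(self.denominator)
        return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))

    def __str__(self):
        if self.denominator == 0:
            return "0/0"
        return f"{self.numerator}/{self.denominator} ({self.percent_rounded}%)"


def proportion(table: ContingencyTable, row, col) -> Optional[Proportion]:
    """Row-conditional proportion count/row-total; None for an empty row."""
    i = table.row_labels.index(row)
    j = table.col_labels.index(col)
    total = int(table.counts[i].sum())
    if total == 0:
        return None
    return Proportion(int(table.counts[i, j]), total)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (point-probability rule:
    the sum of probabilities of all tables with the observed margins whose
    point probability does not exceed the observed table's)."""
    if table.counts.shape != (2, 2):
        raise ResiflexError(
            f"Fisher's exact test requires a 2x2 table, got {table.counts.shape}"
        )
    if np.any(table.counts.sum(axis=0) == 0) or np.any(table.counts.sum(axis=1) == 0):
        raise ResiflexError("Fisher's exact test requires positive margins")
    return float(stats.fisher_exact(table.counts, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# attribute ranking

def _entropy_bits(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _conditional_entropy_bits(attr: np.ndarray, outcome: np.ndarray) -> float:
    h = 0.0
    n = len(attr)
    for v in np.unique(attr):
        sel = attr == v
        h += sel.sum() / n * _entropy_bits(outcome[sel])
    return h


def _encode(col: pd.Series) -> np.ndarray:
    return col.astype(str).to_numpy()


def score_chi2(attr: np.ndarray, outcome: np.ndarray) -> float:
    """Pearson chi-squared statistic (no continuity correction)."""
    tab = pd.crosstab(pd.Series(attr), pd.Series(outcome)).to_numpy()
    if min(tab.shape) < 2:
        return 0.0
    return float(stats.chi2_contingency(tab, correction=False)[0])


def score_info_gain(attr: np.ndarray, outcome: np.ndarray) -> float:
    """H(outcome) - H(outcome | attribute), in bits."""
    return max(0.0, _entropy_bits(outcome) - _conditional_entropy_bits(attr, outcome))


def score_symmetrical_uncertainty(attr: np.ndarray, outcome: np.ndarray) -> float:
    """2 * IG / (H(attr) + H(outcome)); in [0, 1]."""
    ha, ho = _entropy_bits(attr), _entropy_bits(outcome)
    if ha + ho == 0.0:
        return 0.0
    return 2.0 * score_info_gain(attr, outcome) / (ha + ho)


def score_correlation(attr: np.ndarray, outcome: np.ndarray) -> float:
    """|Pearson r| on indicator encodings.

    Binary attributes use a single 0/1 indicator; multi-level attributes
    take the frequency-weighted mean of |r| over one-hot columns.
    """
    y = (outcome == np.unique(outcome)[-1]).astype(np.float64)
    if y.std() == 0.0:
        return 0.0
    levels = np.unique(attr)
    if len(levels) < 2:
        return 0.0
    if len(levels) == 2:
        use, weights = levels[-1:], [1.0]
    else:
        use = levels
        weights = [(attr == l).mean() for l in levels]
    total, wsum = 0.0, 0.0
    for lvl, w in zip(use, weights):
        x = (attr == lvl).astype(np.float64)
        if x.std() == 0.0:
            continue
        r = abs(float(np.corrcoef(x, y)[0, 1]))
        total += w * r
        wsum += w
    return total / wsum if wsum else 0.0


def score_relieff(attr_matrix: np.ndarray, outcome: np.ndarray,
                  k_neighbors: int = 10, sample_size: Optional[int] = None,
                  seed: int = 0) -> np.ndarray:
    """ReliefF weights for all attributes jointly (Kononenko variant).

    Distances are Hamming (overlap) over the categorical attribute matrix;
    for each probe instance the k nearest hits and, per other class, the k
    nearest misses (weighted by prior) pull the weight down or up.  All
    instances are probed when ``sample_size`` is None; otherwise a seeded
    subsample of that size.  Ties in distance are broken by instance order,
    so the result is deterministic.
    """
    n, p = attr_matrix.shape
    # integer-encode once; per-probe diffs keep memory at O(n * p)
    codes = np.empty((n, p), dtype=np.int32)
    for j in range(p):
        _, codes[:, j] = np.unique(attr_matrix[:, j], return_inverse=True)
    classes, class_counts = np.unique(outcome, return_counts=True)
    priors = dict(zip(classes, class_counts / n))
    members_by_class = {c: np.flatnonzero(outcome == c) for c in classes}
    if sample_size is None or sample_size >= n:
        probes = np.arange(n)
    else:
        rng = np.random.default_rng(int(seed) % (2**31))
        probes = np.sort(rng.choice(n, size=sample_size, replace=False))
    w = np.zeros(p)
    m = len(probes)
    for i in probes:
        ci = outcome[i]
        diff_i = codes != codes[i]          # (n, p) Hamming components
        dist_i = diff_i.sum(axis=1)
        for c in classes:
            members = members_by_class[c]
            members = members[members != i]
            if len(members) == 0:
                continue
            k = min(k_neighbors, len(members))
            order = members[np.argsort(dist_i[members], kind="stable")[:k]]
            contrib = diff_i[order].mean(axis=0)
            if c == ci:
                w -= contrib / m
            else:
                w += priors[c] / (1.0 - priors[ci]) * contrib / m
    return w


EVALUATORS = ("chi2", "info_gain", "symmetrical_uncertainty", "correlation",
              "relieff", "filtered")


@dataclass
class AttributeRanking:
    """Ranker output: attributes sorted by descending score."""

    evaluator: str
    ranking: List[Tuple[str, float]]

    @property
    def top(self) -> str:
        return self.ranking[0][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranking, columns=["attribute", "score"])


def rank_attributes(cohort: pd.DataFrame, evaluator: str,
                    outcome: str = OUTCOME,
                    attributes: Sequence[str] = ATTRIBUTES,
                    relieff_k: int = 10,
                    relieff_sample_size: Optional[int] = None,
                    seed: int = 0) -> AttributeRanking:
    """Score each attribute's association with the outcome and sort.

    ``evaluator`` is one of chi2, info_gain, symmetrical_uncertainty,
    correlation, relieff, or filtered (info_gain behind the validation
    filter).  Constant attributes score 0.  Descending scores, ties broken
    by attribute name.  ReliefF probes every instance when the cohort has
    at most 1000 rows, otherwise a seeded subsample of 1000.
    """
    if evaluator not in EVALUATORS:
        raise ResiflexError(f"unknown evaluator {evaluator!r}; "
                            f"choose from {EVALUATORS}")
    if len(cohort) < 2:
        raise ResiflexError("attribute ranking requires at least 2 patients")
    y = _encode(cohort[outcome])
    if len(np.unique(y)) < 2:
        raise ResiflexError("outcome must have both levels for ranking")
    attributes = [a for a in attributes if a in cohort.columns]
    if evaluator == "filtered":
        errors = validate_cohort(cohort)
        if errors:
            raise CohortValidationError(errors)
        evaluator_fn = score_info_gain
    else:
        evaluator_fn = {
            "chi2": score_chi2,
            "info_gain": score_info_gain,
            "symmetrical_uncertainty": score_symmetrical_uncertainty,
            "correlation": score_correlation,
            "relieff": None,
        }[evaluator]
    if evaluator == "relieff":
        mat = np.column_stack([_encode(cohort[a]) for a in attributes])
        if relieff_sample_size is None and len(cohort) > 1000:
            relieff_sample_size = 1000
        scores = score_relieff(mat, y, k_neighbors=relieff_k,
                               sample_size=relieff_sample_size, seed=seed)
        pairs = list(zip(attributes, scores.tolist()))
    else:
        pairs = [(a, float(evaluator_fn(_encode(cohort[a]), y)))
                 for a in attributes]
    pairs.sort(key=lambda kv: (-kv[1], kv[0]))
    return AttributeRanking(evaluator, pairs)


def rank_all(cohort: pd.DataFrame, **kw) -> Dict[str, AttributeRanking]:
    return {ev: rank_attributes(cohort, ev, **kw) for ev in EVALUATORS}
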