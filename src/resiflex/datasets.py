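"""Packaged cohort fixture reconstructed from the published summary counts.

The study's per-patient registry is not public; what is published are
summary counts (cohort margins, the mutation-by-inhibitor T790M table, and
a handful of cross-tabulated sentences).  :func:`paper_cohort` builds a
deterministic 68-patient table that reproduces every one of those printed
counts exactly:

* 27/68 acquired T790M overall;
* mutation groups 31 / 3 / 3 / 31 (delE746_A750, exon19-LRE-other,
  exon19-non-LRE, L858R) with 19 / 0 / 0 / 8 T790M-positive;
* the full mutation x TKI exposure table (gefitinib 17/28, 0/3, 7/23;
  erlotinib 4/9, 0/1, 0/5; afatinib 4/6, 0/0, 1/5; overall 19/31, 0/3,
  8/31 and 27/65 — the 3 exon19-LRE-other patients are the ones excluded
  from that table);
* bone metastasis 34/68, of whom 21 acquired T790M (6 of the 34 without);
* 18 patients with both bone metastasis and delE746_A750, 15 T790M-positive;
* 15 single-site patients, 14 of them T790M-negative;
* first-line TKI 54 / 7 / 7 (gefitinib / erlotinib / afatinib) and
  per-drug exposure totals 56 / 17 / 12 across all lines;
* metastatic-site margins (lung 59, pleura 30, brain 15, liver 11, bone 34,
  distant nodes 18) and site-count distribution 15/22/19/9/3 for 1..5 sites;
* sex 14/54, smoking 58/2/8, chemotherapy lines 44/16/6/2 for 0..3.

Cells not pinned by any published count (e.g. which particular patient is
male) are filled deterministically and arbitrarily; analyses must only
ever rely on the constrained counts above.  The published tables are not
perfectly mutually consistent (the per-patient TKI-line histogram implied
here is 54/11/3 versus a printed 53/12/3); the exposure table and drug
margins, which the analyses consume, take precedence.

This module is a synthetic stand-in for the unpublished registry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .cohort import ATTRIBUTES, OUTCOME, Proportion

DELE746 = "exon19_LRE_delE746_A750"
LRE_OTHER = "exon19_LRE_other"
NON_LRE = "exon19_nonLRE"
L858R = "L858R"

G, E, A = "gefitinib", "erlotinib", "afatinib"

#: (mutation, t790m, tki sequence) -> multiplicity; bone counts separate
_GROUPS: List[Tuple[str, bool, Tuple[str, ...], int]] = [
    (DELE746, True, (G,), 13),
    (DELE746, True, (G, E), 2),
    (DELE746, True, (A, G), 2),
    (DELE746, True, (E, A), 1),
    (DELE746, True, (A, E), 1),
    (DELE746, False, (G, E, A), 2),
    (DELE746, False, (G,), 7),
    (DELE746, False, (G, E), 2),
    (DELE746, False, (E,), 1),
    (NON_LRE, False, (G,), 2),
    (NON_LRE, False, (G, E), 1),
    (LRE_OTHER, False, (G, E), 1),
    (LRE_OTHER, False, (G,), 1),
    (LRE_OTHER, False, (E, A), 1),
    (L858R, True, (G,), 7),
    (L858R, True, (A,), 1),
    (L858R, False, (G, E, A), 1),
    (L858R, False, (G,), 15),
    (L858R, False, (E,), 4),
    (L858R, False, (A,), 3),
]

#: bone-metastasis count within each (mutation, t790m) stratum
_BONE_BY_STRATUM: Dict[Tuple[str, bool], int] = {
    (DELE746, True): 15,
    (DELE746, False): 3,
    (NON_LRE, False): 1,
    (LRE_OTHER, False): 1,
    (L858R, True): 6,
    (L858R, False): 8,
}

_SITE_MARGINS = [("lung_met", 59), ("pleural_met", 30), ("distant_ln_met", 18),
                 ("brain_met", 15), ("liver_met", 11)]
_N_SITES_MULTISET = {1: 15, 2: 22, 3: 19, 4: 9, 5: 3}
_CHEMO_LINES = {0: 44, 1: 16, 2: 6, 3: 2}
_N_MALE, _SMOKING = 14, {"never": 58, "chronic": 2, "ex": 8}


def _ages() -> List[int]:
    lower = [47 + (19 * i) // 33 for i in range(34)]   # 47 .. 66
    upper = [66 + (21 * i) // 33 for i in range(34)]   # 66 .. 87
    return lower + upper


def paper_cohort() -> pd.DataFrame:
    """Build the 68-patient fixture (bit-stable across runs and platforms)."""
    rows = []
    for mut, t790m, tkis, count in _GROUPS:
        for _ in range(count):
            rows.append({"initial_egfr_mutation": mut, OUTCOME: t790m,
                         "_tkis": tkis})
    df = pd.DataFrame(rows)

    # bone flags: first k patients of each (mutation, outcome) stratum
    bone = np.zeros(len(df), dtype=bool)
    for (mut, out), k in _BONE_BY_STRATUM.items():
        idx = df.index[(df["initial_egfr_mutation"] == mut)
                       & (df[OUTCOME] == out)][:k]
        bone[idx] = True
    df["bone_met"] = bone

    # single-site patients: 1 T790M-positive (L858R, no bone), 14 negative
    one_site = np.zeros(len(df), dtype=bool)
    pos = df.index[(df["initial_egfr_mutation"] == L858R) & df[OUTCOME]
                   & ~df["bone_met"]][:1]
    neg_a = df.index[(df["initial_egfr_mutation"] == DELE746) & ~df[OUTCOME]
                     & ~df["bone_met"]][:4]
    neg_b = df.index[(df["initial_egfr_mutation"] == L858R) & ~df[OUTCOME]
                     & ~df["bone_met"]][:10]
    one_site[pos] = one_site[neg_a] = one_site[neg_b] = True
    if one_site.sum() != _N_SITES_MULTISET[1]:
        raise AssertionError("fixture construction: single-site selection failed")

    # number of metastatic sites: larger counts preferentially to
    # bone-positive patients (arbitrary fill, deterministic)
    n_sites = np.zeros(len(df), dtype=np.int64)
    n_sites[one_site] = 1
    remaining = [n for n, k in _N_SITES_MULTISET.items() if n > 1
                 for _ in range(k)]
    remaining.sort(reverse=True)                       # 5,5,5,4...,2
    others = sorted(np.flatnonzero(~one_site),
                    key=lambda i: (not bone[i], i))    # bone patients first
    for i, n in zip(others, remaining):
        n_sites[i] = n
    df["number_sites_met"] = n_sites

    # fill the remaining site flags to hit the published margins exactly
    capacity = n_sites - bone.astype(np.int64)
    for site, quota in _SITE_MARGINS:
        flags = np.zeros(len(df), dtype=bool)
        order = sorted(range(len(df)), key=lambda i: (-capacity[i], i))
        chosen = [i for i in order if capacity[i] > 0][:quota]
        if len(chosen) < quota:
            raise AssertionError(f"fixture construction: cannot place {site}")
        flags[chosen] = True
        capacity[chosen] -= 1
        df[site] = flags
    if capacity.sum() != 0:
        raise AssertionError("fixture construction: site capacities not exhausted")

    # TKI columns
    df["first_tki"] = [t[0] for t in df["_tkis"]]
    df["second_tki"] = [t[1] if len(t) > 1 else "" for t in df["_tkis"]]
    df["third_tki"] = [t[2] if len(t) > 2 else "" for t in df["_tkis"]]
    df["number_lines_tki"] = [len(t) for t in df["_tkis"]]
    df["second_tki_used"] = df["number_lines_tki"] >= 2
    df["third_tki_used"] = df["number_lines_tki"] >= 3
    df = df.drop(columns="_tkis")

    # unconstrained demographics: deterministic internal shuffles
    rng = np.random.default_rng(20170068)
    ages = np.asarray(_ages())[rng.permutation(len(df))]
    for thr in (55, 60, 65, 70, 75, 80):
        df[f"age_{thr}"] = ages >= thr
    sex = np.asarray(["female"] * len(df), dtype=object)
    sex[rng.permutation(len(df))[:_N_MALE]] = "male"
    df["sex"] = sex
    smoking = np.asarray(sum(([k] * v for k, v in _SMOKING.items()), []),
                         dtype=object)
    df["smoking"] = smoking[rng.permutation(len(df))]
    chemo = np.asarray(sum(([k] * v for k, v in _CHEMO_LINES.items()), []))
    df["number_lines_chemo"] = chemo[rng.permutation(len(df))]
    df["first_chemo_used"] = df["number_lines_chemo"] >= 1
    df["second_chemo_used"] = df["number_lines_chemo"] >= 2
    df["third_chemo_used"] = df["number_lines_chemo"] >= 3

    ordered = [c for c in ATTRIBUTES] + ["second_tki", "third_tki", OUTCOME]
    return df[ordered].reset_index(drop=True)


# ---------------------------------------------------------------------------
# mutation x TKI exposure table

TABLE_MUTATIONS = (DELE746, NON_LRE, L858R)
TABLE_TKIS = (G, E, A)


def _tki_set(row) -> set:
    return {t for t in (row["first_tki"], row.get("second_tki", ""),
                        row.get("third_tki", "")) if t}


def mutation_tki_table(cohort: pd.DataFrame
                       ) -> Dict[str, Dict[str, Optional[Proportion]]]:
    """Probability of the outcome per mutation and per TKI exposure.

    Rows: each inhibitor (a patient counts in every row of a drug they
    received, any line) plus ``overall`` (each patient once).  Columns: the
    three mutation groups plus ``overall``.  Patients whose mutation is
    ``exon19_LRE_other`` are excluded (65 evaluable).  A cell with an empty
    denominator is returned as a 0/0 :class:`Proportion` (printed blank).
    """
    ev = cohort[cohort["initial_egfr_mutation"].isin(TABLE_MUTATIONS)]
    out: Dict[str, Dict[str, Optional[Proportion]]] = {}
    for tki in TABLE_TKIS:
        sel = ev[[tki in _tki_set(r) for _, r in ev.iterrows()]]
        row: Dict[str, Optional[Proportion]] = {}
        for mut in TABLE_MUTATIONS:
            sub = sel[sel["initial_egfr_mutation"] == mut]
            row[mut] = Proportion(int(sub[OUTCOME].sum()), len(sub))
        row["overall"] = Proportion(int(sel[OUTCOME].sum()), len(sel))
        out[tki] = row
    row = {}
    for mut in TABLE_MUTATIONS:
        sub = ev[ev["initial_egfr_mutation"] == mut]
        row[mut] = Proportion(int(sub[OUTCOME].sum()), len(sub))
    row["overall"] = Proportion(int(ev[OUTCOME].sum()), len(ev))
    out["overall"] = row
    return out


@dataclass
class ResultsProportions:
    """The cross-tabulated prose proportions of the cohort analysis."""

    overall: Proportion                 # acquired T790M among all patients
    bone: Proportion                    # T790M among bone-metastasis patients
    no_bone: Proportion                 # T790M among patients without it
    bone_share_of_positive: Proportion  # bone-met patients among T790M+
    bone_and_dele746: Proportion        # T790M among bone & delE746_A750
    single_site_negative: Proportion    # no T790M among single-site patients


def results_proportions(cohort: pd.DataFrame) -> ResultsProportions:
    t = cohort[OUTCOME].astype(bool)
    bone = cohort["bone_met"].astype(bool)
    dele = cohort["initial_egfr_mutation"] == DELE746
    one = cohort["number_sites_met"] == 1
    return ResultsProportions(
        overall=Proportion(int(t.sum()), len(cohort)),
        bone=Proportion(int((t & bone).sum()), int(bone.sum())),
        no_bone=Proportion(int((t & ~bone).sum()), int((~bone).sum())),
        bone_share_of_positive=Proportion(int((t & bone).sum()), int(t.sum())),
        bone_and_dele746=Proportion(int((t & bone & dele).sum()),
                                    int((bone & dele).sum())),
        single_site_negative=Proportion(int((~t & one).sum()), int(one.sum())),
    )
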