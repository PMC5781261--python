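"""Per-iteration taxonomic profiles and homogeneity statistics.

Each workflow iteration contributes a row of read counts per taxon (reads
assigned to contigs of that taxon). A chi-square test for homogeneity asks
whether all iterations share one underlying taxon distribution; where it
rejects, pairwise two-proportion Z-tests (pooled variance, two-sided)
locate the taxa and iteration pairs that shifted, with Benjamini-Hochberg
correction over the whole Z-test batch. Iterations are then labelled with
compact letters: bars sharing a letter are not significantly different.

Contig taxon labels come either from simulation truth (majority vote of
the aligned reads' source genomes) or from a user-supplied contig -> taxon
table; no database-driven annotation happens here.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import AlignmentHit
from .errors import SphericalError

UNCLASSIFIED = "unclassified"


@dataclass
class ProfileTable:
    """Iterations x taxa read-count contingency table."""

    counts: pd.DataFrame  # index = iteration labels, columns = taxa

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("profile counts must be non-negative")

    @property
    def iterations(self) -> list:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="iteration")

    @classmethod
    def from_tsv(cls, path) -> "ProfileTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if df.shape[1] < 1:
            raise SphericalError(f"{path}: profile table has no taxon columns")
        return cls(counts=df.astype(int))


@dataclass
class TestResult:
    """One hypothesis test outcome."""

    statistic: float
    p_value: float
    df: Optional[int] = None
    q_value: Optional[float] = None
    flag: Optional[str] = None


def profile_from_labels(
    hits_per_iteration: Mapping[int, Sequence[AlignmentHit]],
    contig_taxa: Mapping[str, str],
) -> ProfileTable:
    """counts[i, t] = hits in iteration i on contigs labelled t.

    Contigs missing from ``contig_taxa`` count as ``unclassified``.
    """
    rows = {}
    for it, hits in sorted(hits_per_iteration.items()):
        tally: Counter[str] = Counter()
        for h in hits:
            tally[contig_taxa.get(h.contig_id, UNCLASSIFIED)] += 1
        rows[it] = tally
    taxa = sorted({t for tally in rows.values() for t in tally})
    df = pd.DataFrame(
        [[rows[it].get(t, 0) for t in taxa] for it in rows],
        index=list(rows),
        columns=taxa,
        dtype=int,
    )
    return ProfileTable(counts=df)


def contig_taxa_from_truth(
    hits: Sequence[AlignmentHit], read_taxa: Mapping[str, str]
) -> dict[str, str]:
    """Label each contig by majority vote of its aligned reads' truth taxa;
    ties break lexicographically; contigs with no labelled hits are
    ``unclassified`` (callers add unhit contigs themselves if needed)."""
    votes: dict[str, Counter] = {}
    for h in hits:
        taxon = read_taxa.get(h.read_id)
        if taxon is None:
            continue
        votes.setdefault(h.contig_id, Counter())[taxon] += 1
    labels = {}
    for cid, tally in votes.items():
        top = max(tally.values())
        labels[cid] = min(t for t, n in tally.items() if n == top)
    return labels


def chi2_homogeneity(table: ProfileTable) -> TestResult:
    """Pearson chi-square test that all iterations share one taxon
    distribution. All-zero rows/columns are dropped first; a table left
    with fewer than 2 rows or columns is degenerate."""
    obs = table.counts.values.astype(float)
    obs = obs[obs.sum(axis=1) > 0]
    obs = obs[:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise SphericalError(
            "degenerate contingency table: need >=2 non-zero rows and columns"
        )
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, dof))
    return TestResult(statistic=stat, p_value=p, df=dof)


def two_prop_ztest(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Two-sided pooled two-proportion Z-test.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p pooled. A pooled
    proportion of exactly 0 or 1 has zero variance; p=1 by convention,
    flagged 'degenerate'.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 <= 0 or n2 <= 0:
        raise ValueError("need 0 <= x <= n and n > 0 in both groups")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TestResult(statistic=0.0, p_value=1.0, flag="degenerate")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = float(2 * sps.norm.sf(abs(z)))
    return TestResult(statistic=float(z), p_value=p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class CompareResult:
    """Homogeneity test plus pairwise breakdown and letter groups."""

    homogeneity: TestResult
    ztests: pd.DataFrame  # iter_a, iter_b, taxon, z, p, q
    letters: dict  # iteration -> letter
    alpha: float

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "chi2": {
                "statistic": self.homogeneity.statistic,
                "df": self.homogeneity.df,
                "p_value": self.homogeneity.p_value,
            },
            "letters": {str(k): v for k, v in self.letters.items()},
            "ztests": self.ztests.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def compare_iterations(table: ProfileTable, alpha: float = 0.05) -> CompareResult:
    """Homogeneity test; on rejection, all pairwise per-taxon Z-tests with
    BH correction across the full batch, then greedy letter grouping over
    the non-significance graph (deterministic by iteration order)."""
    homog = chi2_homogeneity(table)
    iterations = table.iterations
    cols = ["iter_a", "iter_b", "taxon", "z", "p", "q"]
    if homog.p_value >= alpha:
        letters = {it: "a" for it in iterations}
        return CompareResult(
            homogeneity=homog,
            ztests=pd.DataFrame(columns=cols),
            letters=letters,
            alpha=alpha,
        )

    counts = table.counts
    row_totals = counts.sum(axis=1)
    records = []
    for ai in range(len(iterations)):
        for bi in range(ai + 1, len(iterations)):
            ia, ib = iterations[ai], iterations[bi]
            n1, n2 = int(row_totals[ia]), int(row_totals[ib])
            if n1 == 0 or n2 == 0:
                continue
            for taxon in table.taxa:
                res = two_prop_ztest(
                    int(counts.at[ia, taxon]), n1, int(counts.at[ib, taxon]), n2
                )
                records.append((ia, ib, taxon, res.statistic, res.p_value))
    zdf = pd.DataFrame(records, columns=cols[:-1])
    zdf["q"] = bh_adjust(zdf["p"].values) if len(zdf) else []

    sig_pairs = set()
    for (ia, ib), grp in zdf.groupby(["iter_a", "iter_b"]):
        if (grp["q"] < alpha).any():
            sig_pairs.add((ia, ib))
            sig_pairs.add((ib, ia))

    # greedy clique cover of the non-significance graph, iteration order
    groups: list[list] = []
    letters = {}
    for it in iterations:
        for gi, members in enumerate(groups):
            if all((it, other) not in sig_pairs for other in members):
                members.append(it)
                letters[it] = chr(ord("a") + gi)
                break
        else:
            groups.append([it])
            letters[it] = chr(ord("a") + len(groups) - 1)
    return CompareResult(homogeneity=homog, ztests=zdf, letters=letters, alpha=alpha)
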