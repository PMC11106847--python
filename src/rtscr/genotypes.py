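"""Consensus genotyping from replicated PCRs, individual matching, error rates, PID.

Non-invasive samples are amplified in up to four PCR replicates per sample at
a panel of microsatellite loci.  A heterozygous consensus call requires the
identical allele pair in at least two replicates; a homozygous call requires
the identical homozygote in at least three.  Samples with more than 14 called
loci are accepted; identical accepted genotypes are merged into individuals.
Probability-of-identity statistics (PID, PIDsibs) quantify how likely two
different individuals are to share a multilocus genotype by chance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConsensusGenotype",
    "ErrorRates",
    "IdentityStats",
    "build_consensus",
    "consensus_panel",
    "match_individuals",
    "error_rates",
    "probability_of_identity",
    "pid_random_subsets",
    "read_genotypes",
    "read_allele_frequencies",
    "allele_frequencies_from_consensus",
    "sampling_summary",
]

MIN_CALLED_LOCI = 15        # "more than 14 loci": >= 15 called loci accepted


@dataclass
class ConsensusGenotype:
    sample_id: str
    calls: dict                 # locus -> (a1, a2) sorted tuple, or absent
    n_called: int
    accepted: bool
    sex: str | None = None      # "M" / "F" / None when no sex marker was typed

    def call(self, locus: str):
        return self.calls.get(locus)


def _pair(a1, a2):
    if a1 is None or a2 is None or (isinstance(a1, float) and np.isnan(a1)):
        return None
    return tuple(sorted((str(a1), str(a2))))


def build_consensus(
    replicates: pd.DataFrame,
    min_called: int = MIN_CALLED_LOCI,
    male_marker: str | None = None,
) -> ConsensusGenotype:
    """Consensus multilocus genotype for one sample from its PCR replicates.

    ``replicates`` is long form: columns sample_id, replicate, locus, allele1,
    allele2 (missing alleles as None/NaN).  Per locus, a heterozygous pair
    seen in >= 2 replicates or a homozygote seen in >= 3 becomes the call;
    otherwise the locus stays missing.  Two conflicting qualifying calls at
    one locus cannot happen with four replicates (2 + 3 > 4 for het vs hom);
    two distinct heterozygotes twice each leaves the locus missing.

    ``male_marker`` names a locus treated as a Y-linked presence marker: the
    sample is called male iff it amplifies in >= 2 replicates.
    """
    sids = replicates["sample_id"].unique()
    if len(sids) != 1:
        raise ValueError("build_consensus expects the replicates of exactly one sample")
    nrep = replicates["replicate"].nunique()
    if not 1 <= nrep <= 4:
        raise ValueError("expected 1-4 amplification replicates")
    calls: dict = {}
    sex = None
    for locus, grp in replicates.groupby("locus", sort=False):
        pairs = [p for p in (_pair(a, b) for a, b in zip(grp["allele1"], grp["allele2"])) if p]
        if locus == male_marker:
            sex = "M" if len(pairs) >= 2 else "F"
            continue
        counts = Counter(pairs)
        qualifying = [
            p for p, c in counts.items()
            if (p[0] != p[1] and c >= 2) or (p[0] == p[1] and c >= 3)
        ]
        het = [p for p in qualifying if p[0] != p[1]]
        hom = [p for p in qualifying if p[0] == p[1]]
        assert not (het and hom), (
            "impossible consensus conflict: a 2x heterozygote and a 3x homozygote "
            "cannot coexist within four replicates"
        )
        if len(qualifying) == 1:
            calls[locus] = qualifying[0]
        # 0 or >1 qualifying (two distinct heterozygotes): locus stays missing
    n_called = len(calls)
    return ConsensusGenotype(str(sids[0]), calls, n_called, n_called >= min_called, sex)


def consensus_panel(
    table: pd.DataFrame, min_called: int = MIN_CALLED_LOCI, male_marker: str | None = None
) -> list[ConsensusGenotype]:
    """Consensus genotypes for every sample in a long replicate table."""
    return [
        build_consensus(grp, min_called, male_marker)
        for _, grp in table.groupby("sample_id", sort=False)
    ]


def match_individuals(
    consensus: list[ConsensusGenotype],
    mismatch_tolerance: int = 0,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Merge accepted consensus genotypes that agree at all jointly-called loci.

    Two samples match when they share >= ``min_overlap`` called loci and
    disagree at <= ``mismatch_tolerance`` of them; matching samples are merged
    transitively (union-find).  Individuals are labelled ID01, ID02, ... by
    first appearance, so the labelling is deterministic.  Returns a DataFrame
    (sample_id, individual_id, n_called, sex).
    """
    acc = [c for c in consensus if c.accepted]
    parent = list(range(len(acc)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(acc)):
        for k in range(i + 1, len(acc)):
            shared = acc[i].calls.keys() & acc[k].calls.keys()
            if len(shared) < min_overlap:
                continue
            mism = sum(acc[i].calls[l] != acc[k].calls[l] for l in shared)
            if mism <= mismatch_tolerance:
                ri, rk = find(i), find(k)
                if ri != rk:
                    parent[max(ri, rk)] = min(ri, rk)
    labels: dict[int, str] = {}
    rows = []
    for i, c in enumerate(acc):
        r = find(i)
        if r not in labels:
            labels[r] = f"ID{len(labels) + 1:02d}"
        rows.append((c.sample_id, labels[r], c.n_called, c.sex))
    return pd.DataFrame(rows, columns=["sample_id", "individual_id", "n_called", "sex"])


@dataclass
class ErrorRates:
    """Genotyping error rates: allelic dropout and false alleles, per locus and mean."""

    dropout_per_locus: pd.Series
    false_per_locus: pd.Series

    @property
    def mean_dropout(self) -> float:
        return float(self.dropout_per_locus.dropna().mean())

    @property
    def mean_false_allele(self) -> float:
        return float(self.false_per_locus.dropna().mean())


def error_rates(table: pd.DataFrame, consensus: list[ConsensusGenotype]) -> ErrorRates:
    """Dropout and false-allele rates of the replicates against the consensus.

    Dropout rate at a locus: among replicate observations made where the
    consensus is *heterozygous*, the fraction appearing homozygous.  False
    allele rate: among all replicate observations at called loci, the
    fraction containing an allele absent from the consensus.  Loci with no
    heterozygous consensus observations get a missing dropout rate.
    """
    cons = {c.sample_id: c for c in consensus}
    loci = sorted(table["locus"].unique())
    drop_num = {l: 0 for l in loci}
    drop_den = {l: 0 for l in loci}
    false_num = {l: 0 for l in loci}
    false_den = {l: 0 for l in loci}
    for (sid, locus), grp in table.groupby(["sample_id", "locus"], sort=False):
        c = cons.get(sid)
        if c is None:
            continue
        call = c.call(locus)
        if call is None:
            continue
        het = call[0] != call[1]
        for a, b in zip(grp["allele1"], grp["allele2"]):
            p = _pair(a, b)
            if p is None:
                continue
            false_den[locus] += 1
            if set(p) - set(call):
                false_num[locus] += 1
            if het:
                drop_den[locus] += 1
                if p[0] == p[1]:
                    drop_num[locus] += 1
    dropout = pd.Series(
        {l: (drop_num[l] / drop_den[l]) if drop_den[l] else np.nan for l in loci}
    )
    false = pd.Series(
        {l: (false_num[l] / false_den[l]) if false_den[l] else np.nan for l in loci}
    )
    return ErrorRates(dropout, false)


@dataclass
class IdentityStats:
    """Probability-of-identity statistics; multilocus values are products over loci."""

    pid: float
    pidsibs: float
    per_locus: pd.DataFrame

    def __post_init__(self):
        assert 0.0 <= self.pid <= self.pidsibs <= 1.0 + 1e-12


def _pid_locus(p: np.ndarray) -> tuple[float, float]:
    s2 = float((p**2).sum())
    s4 = float((p**4).sum())
    pid = 2 * s2**2 - s4
    pidsibs = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
    return pid, pidsibs


def probability_of_identity(
    allele_freqs: dict, loci: list[str] | None = None
) -> IdentityStats:
    """PID and PIDsibs from per-locus allele frequencies.

    Per locus, with allele frequencies p_i:
        PID     = 2 (sum p_i^2)^2 - sum p_i^4
        PIDsibs = 1/4 + 1/2 sum p_i^2 + 1/2 (sum p_i^2)^2 - 1/4 sum p_i^4
    Frequencies at each locus must sum to 1 (+- 1e-9).
    """
    loci = list(loci) if loci is not None else list(allele_freqs)
    rows = {}
    for loc in loci:
        p = np.asarray(list(allele_freqs[loc].values()), dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies at {loc} sum to {p.sum()}, not 1")
        rows[loc] = _pid_locus(p)
    per_locus = pd.DataFrame(rows, index=["pid", "pidsibs"]).T
    return IdentityStats(
        float(per_locus["pid"].prod()), float(per_locus["pidsibs"].prod()), per_locus
    )


def pid_random_subsets(
    allele_freqs: dict,
    subset_size: int = 14,
    n_subsets: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """PID/PIDsibs over random locus subsets (e.g. 10 draws of 14 of 20 loci)."""
    loci = list(allele_freqs)
    if subset_size > len(loci):
        raise ValueError("subset size exceeds the number of loci")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_subsets):
        sub = sorted(rng.choice(loci, size=subset_size, replace=False))
        st = probability_of_identity(allele_freqs, sub)
        rows.append({"subset": k, "pid": st.pid, "pidsibs": st.pidsibs, "loci": ",".join(sub)})
    return pd.DataFrame(rows)


def allele_frequencies_from_consensus(consensus: list[ConsensusGenotype]) -> dict:
    """Empirical allele frequencies per locus from accepted consensus genotypes."""
    counts: dict[str, Counter] = {}
    for c in consensus:
        if not c.accepted:
            continue
        for loc, (a1, a2) in c.calls.items():
            counts.setdefault(loc, Counter()).update([a1, a2])
    out = {}
    for loc, cnt in counts.items():
        tot = sum(cnt.values())
        out[loc] = {a: c / tot for a, c in sorted(cnt.items())}
    return out


def read_genotypes(path: str) -> pd.DataFrame:
    """Long-form replicate genotype CSV: sample_id, replicate, locus, allele1, allele2."""
    df = pd.read_csv(path)
    missing = {"sample_id", "replicate", "locus", "allele1", "allele2"} - set(df.columns)
    if missing:
        raise ValueError(f"genotype CSV missing columns: {sorted(missing)}")
    return df


def read_allele_frequencies(path: str) -> dict:
    """Allele frequency CSV (locus, allele, freq) -> nested dict."""
    df = pd.read_csv(path)
    out: dict = {}
    for _, row in df.iterrows():
        out.setdefault(row["locus"], {})[str(row["allele"])] = float(row["freq"])
    return out


def sampling_summary(n_samples: int, assignment: pd.DataFrame) -> dict:
    """Survey-level genotyping summary from a sample -> individual assignment.

    Returns genotyping success (accepted / collected), the mean number of
    captures per individual, and the male:female sex ratio (majority call per
    individual; individuals without sex calls are left out of the ratio).
    """
    n_acc = len(assignment)
    n_ind = assignment["individual_id"].nunique()
    sex_by_ind = (
        assignment.dropna(subset=["sex"])
        .groupby("individual_id")["sex"]
        .agg(lambda s: s.mode().iloc[0])
        if "sex" in assignment and assignment["sex"].notna().any()
        else pd.Series(dtype=object)
    )
    males = int((sex_by_ind == "M").sum())
    females = int((sex_by_ind == "F").sum())
    return {
        "n_samples": int(n_samples),
        "n_genotyped": int(n_acc),
        "success_rate": n_acc / n_samples if n_samples else np.nan,
        "n_individuals": int(n_ind),
        "mean_recaptures": n_acc / n_ind if n_ind else np.nan,
        "males": males,
        "females": females,
        "sex_ratio": males / females if females else np.nan,
    }
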