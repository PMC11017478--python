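"""Census size estimation and inter-population movement detection.

Two-session Lincoln–Petersen abundance estimation from tag histories, with
the Chapman bias-corrected variant as the default (it stays finite when no
marked fish are recaptured, which happens in the smallest caves), plus
detection of tagged individuals recaptured in a different population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CensusEstimate",
    "lincoln_petersen",
    "census_all",
    "detect_migrants",
]


@dataclass
class CensusEstimate:
    population: str | None
    M: int
    C: int
    R: int
    estimate: float
    variant: str
    ci_low: float
    ci_high: float
    classic_estimate: float | None = None
    flags: tuple = ()


def lincoln_petersen(M: int, C: int, R: int, variant: str = "chapman",
                     ci: float = 0.95) -> CensusEstimate:
    """Two-sample abundance estimate.

    Classic: ``N = M C / R`` (undefined at R = 0).  Chapman:
    ``N = (M+1)(C+1)/(R+1) - 1`` (always defined, unbiased when
    ``M + C >= N``).  The CI is a normal approximation on the Chapman
    variance ``(M+1)(C+1)(M-R)(C-R) / ((R+1)^2 (R+2))``.
    """
    if M < 0 or C < 0 or R < 0:
        raise ValueError("M, C, R must be non-negative")
    if R > min(M, C):
        raise ValueError("recaptures exceed marked or captured count")
    chapman = (M + 1) * (C + 1) / (R + 1) - 1
    classic = M * C / R if R > 0 else np.nan
    var = (M + 1) * (C + 1) * (M - R) * (C - R) / ((R + 1) ** 2 * (R + 2))
    z = stats.norm.ppf(0.5 + ci / 2)
    half = z * np.sqrt(var)
    flags = []
    if R == 0:
        flags.append("no_recaptures")
    if variant == "chapman":
        est = chapman
    elif variant == "classic":
        est = classic
        if R == 0:
            flags.append("classic_undefined")
    else:
        raise ValueError(f"unknown variant {variant!r}")
    lo = max(chapman - half, float(M + C - R))  # at least the distinct fish seen
    return CensusEstimate(
        population=None, M=int(M), C=int(C), R=int(R),
        estimate=float(est), variant=variant,
        ci_low=float(lo), ci_high=float(chapman + half),
        classic_estimate=float(classic) if R > 0 else None,
        flags=tuple(flags),
    )


REQUIRED_COLUMNS = ("tag_id", "population", "session", "event")


def _check_histories(histories: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(histories.columns)
    if missing:
        raise ValueError(f"capture-history table lacks columns: {sorted(missing)}")
    h = histories.copy()
    h["session"] = h["session"].astype(int)
    return h


def census_all(histories: pd.DataFrame, variant: str = "chapman") -> pd.DataFrame:
    """Per-population abundance estimates from a capture-history table.

    Sessions are pooled over adjacent pairs: for each consecutive session
    pair, M = individuals captured in the earlier session, C = captured in
    the later one, R = seen in both; the pair-wise tallies are summed and a
    single two-sample estimate computed.  Populations with a single session
    are excluded with a flag; populations with zero later-session captures
    are flagged with no estimate.
    """
    h = _check_histories(histories)
    rows = []
    for pop, grp in h.groupby("population", sort=False):
        sessions = sorted(grp["session"].unique())
        if len(sessions) < 2:
            rows.append({"population": pop, "M": np.nan, "C": np.nan, "R": np.nan,
                         "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "note": "single_session"})
            continue
        M = C = R = 0
        for s1, s2 in zip(sessions[:-1], sessions[1:]):
            tags1 = set(grp.loc[grp["session"] == s1, "tag_id"])
            tags2 = set(grp.loc[grp["session"] == s2, "tag_id"])
            M += len(tags1)
            C += len(tags2)
            R += len(tags1 & tags2)
        if C == 0:
            rows.append({"population": pop, "M": M, "C": 0, "R": 0,
                         "estimate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "note": "no_second_session_captures"})
            continue
        est = lincoln_petersen(M, C, R, variant=variant)
        rows.append({"population": pop, "M": M, "C": C, "R": R,
                     "estimate": est.estimate, "ci_low": est.ci_low,
                     "ci_high": est.ci_high, "note": ";".join(est.flags)})
    return pd.DataFrame(rows).set_index("population")


def detect_migrants(histories: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Tags observed in more than one population, per unordered pair.

    A migrant is an individual whose tag appears in at least two distinct
    populations; it is counted once for every unordered pair of populations
    it was seen in.  Returns the per-pair count table and summary statistics
    (mean, SD, median) over pairs with at least one migrant.
    """
    h = _check_histories(histories)
    pair_counts: dict[tuple, int] = {}
    for _, grp in h.groupby("tag_id", sort=False):
        pops = sorted(set(grp["population"]))
        if len(pops) < 2:
            continue
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                key = (pops[i], pops[j])
                pair_counts[key] = pair_counts.get(key, 0) + 1
    pairs = pd.DataFrame(
        [{"pop_a": a, "pop_b": b, "migrants": n} for (a, b), n in sorted(pair_counts.items())],
        columns=["pop_a", "pop_b", "migrants"],
    )
    if len(pairs):
        counts = pairs["migrants"]
        summary = pd.Series({
            "n_pairs": float(len(pairs)),
            "mean": float(counts.mean()),
            "sd": float(counts.std(ddof=1)) if len(counts) > 1 else np.nan,
            "median": float(counts.median()),
        })
    else:
        summary = pd.Series({"n_pairs": 0.0, "mean": np.nan, "sd": np.nan, "median": np.nan})
    return pairs, summary
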