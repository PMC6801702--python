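"""Statistical comparison of predicted cleavage probabilities to observations.

The central device is intra-substrate z-standardization of per-bond
cleavage counts — every enumerable scissile bond of a substrate enters,
unobserved bonds as zeros — which makes cut frequencies comparable across
substrates of differing length and concentration.  Standardized counts are
then grouped into five fixed prediction-probability bins and compared with
a heteroscedastic (Welch) one-way ANOVA and Tukey–Kramer post-hoc letters.
Auxiliary summaries cover prediction coverage, peptide length windows
relevant to HLA presentation, signed distances from observed cuts to
high-probability sites (a carboxypeptidase signature), and Ward clustering
of sample peptide repertoires for quality control.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .digest import CONDITION_KEYS

#: the five prediction-probability bins, labelled as conventionally printed
PROBABILITY_BIN_LABELS = ["0-0.19", "0.2-0.39", "0.4-0.59", "0.6-0.79", "0.8-1"]
_BIN_EDGES = np.array([0.2, 0.4, 0.6, 0.8])


def cso_positions(sequence: str) -> list[int]:
    """P1' positions of every full-window scissile bond of a substrate."""
    L = len(sequence)
    return list(range(5, L - 2)) if L >= 8 else []


def z_standardize(events: pd.DataFrame, bond_positions: dict[str, list[int]],
                  keys: list[str] | None = None) -> pd.DataFrame:
    """Intra-substrate z-standardization of per-bond cleavage counts.

    Within each (substrate, cathepsin, time, pH) stratum present in
    ``events``, every bond position of the substrate enters — bonds with no
    observed event as count 0 — and counts are transformed to zero mean and
    unit sample standard deviation.  Zero-variance strata get all-zero
    z-scores and are flagged ``constant``; single-bond strata are flagged
    and should be excluded from downstream tests.

    Parameters
    ----------
    events : tidy event table (substrate_id, cathepsin, time_h, ph,
        p1prime, count)
    bond_positions : substrate_id -> list of P1' positions constituting the
        full enumerable bond set (see :func:`cso_positions`)
    """
    keys = keys or CONDITION_KEYS
    strata = events[keys].drop_duplicates()
    out = []
    for _, stratum in strata.iterrows():
        sub_id = stratum["substrate_id"]
        positions = np.asarray(bond_positions[sub_id])
        mask = np.ones(len(events), dtype=bool)
        for k in keys:
            mask &= events[k] == stratum[k]
        observed = events[mask].set_index("p1prime")["count"]
        counts = np.array([float(observed.get(p, 0.0)) for p in positions])
        frame = pd.DataFrame({k: stratum[k] for k in keys} |
                             {"p1prime": positions, "count": counts})
        flag = ""
        if len(positions) < 2:
            frame["zscore"] = 0.0
            flag = "singleton"
        else:
            sd = counts.std(ddof=1)
            if sd == 0:
                frame["zscore"] = 0.0
                flag = "constant"
            else:
                frame["zscore"] = (counts - counts.mean()) / sd
        frame["flag"] = flag
        out.append(frame)
    if not out:
        return pd.DataFrame(columns=keys + ["p1prime", "count", "zscore", "flag"])
    return pd.concat(out, ignore_index=True)


def bin_by_probability(probabilities) -> pd.Categorical:
    """Assign each probability to one of the five fixed bins.

    Bins are half-open at 0.2 steps with the top bin closed:
    [0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1.0].
    Probabilities are binned at full precision.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        bad = p[(p < 0) | (p > 1)][0]
        raise ValueError(f"probability {bad} outside [0, 1]")
    idx = np.digitize(p, _BIN_EDGES)
    return pd.Categorical.from_codes(idx, categories=PROBABILITY_BIN_LABELS,
                                     ordered=True)


def welch_anova(groups) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns ``(F, df1, df2, p)`` with the Welch–Satterthwaite denominator
    degrees of freedom.  Groups with fewer than 2 observations or zero
    variance are dropped with a warning; fewer than 2 usable groups is an
    error.
    """
    usable = []
    for g in groups:
        g = np.asarray(g, dtype=float)
        if len(g) < 2 or g.var(ddof=1) == 0:
            warnings.warn("dropping degenerate group (n < 2 or zero variance)")
            continue
        usable.append(g)
    k = len(usable)
    if k < 2:
        raise ValueError("welch_anova needs >= 2 usable groups")
    n = np.array([len(g) for g in usable], dtype=float)
    m = np.array([g.mean() for g in usable])
    v = np.array([g.var(ddof=1) for g in usable])
    w = n / v
    W = w.sum()
    grand = (w * m).sum() / W
    num = ((w * (m - grand) ** 2).sum()) / (k - 1)
    lam = 3.0 * ((1 - w / W) ** 2 / (n - 1)).sum() / (k**2 - 1)
    F = num / (1.0 + 2.0 * lam * (k - 2) / 3.0)
    df1 = float(k - 1)
    df2 = 1.0 / lam
    p = float(sps.f.sf(F, df1, df2)) if F > 0 else 1.0
    return float(F), df1, float(df2), p


def tukey_kramer(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """Tukey–Kramer pairwise comparisons with a compact letter display.

    Pairwise differences are tested against studentized-range quantiles
    with the Tukey–Kramer unequal-n correction.  Letters are assigned by
    the insert-and-absorb algorithm so that groups sharing a letter are not
    significantly different at ``alpha``.

    Returns a frame with one row per group: group, n, mean, letters; the
    pairwise table is attached as ``result.attrs["pairwise"]``.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("tukey_kramer needs >= 2 groups")
    values = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairwise = pd.DataFrame(res.summary().data[1:],
                            columns=res.summary().data[0])

    significant = []
    for (i, j), reject in zip(
            [(a, b) for a in range(len(names)) for b in range(a + 1, len(names))],
            res.reject):
        if reject:
            significant.append((names[i], names[j]))

    # insert-and-absorb compact letter display
    letter_sets: list[set[str]] = [set(names)]
    for a, b in significant:
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb subsets and duplicates
        letter_sets = []
        for s in sorted(new_sets, key=len, reverse=True):
            if s and not any(s <= t for t in letter_sets):
                letter_sets.append(s)
    order = {g: i for i, g in enumerate(names)}
    letter_sets.sort(key=lambda s: min(order[g] for g in s))

    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    rows = []
    for g in names:
        letters = "".join(alphabet[i] for i, s in enumerate(letter_sets) if g in s)
        vals = np.asarray(groups[g], dtype=float)
        rows.append({"group": g, "n": len(vals), "mean": vals.mean(),
                     "letters": letters})
    out = pd.DataFrame(rows)
    out.attrs["pairwise"] = pairwise
    return out


def binned_comparison(profile: pd.DataFrame, zscored: pd.DataFrame,
                      alpha: float = 0.05) -> dict:
    """Bin standardized cut counts by predicted probability and test the trend.

    Joins a cleavage-probability profile to a z-standardized event table on
    (substrate, P1'), assigns the five probability bins, and runs Welch
    ANOVA plus Tukey–Kramer letters over the per-bin z-score samples.
    """
    merged = zscored.merge(
        profile[["substrate_id", "p1prime", "probability"]],
        on=["substrate_id", "p1prime"], how="inner")
    merged["bin"] = bin_by_probability(merged["probability"])
    groups = {str(label): grp["zscore"].to_numpy()
              for label, grp in merged.groupby("bin", observed=True)}
    usable = {k: v for k, v in groups.items()
              if len(v) >= 2 and np.asarray(v).var(ddof=1) > 0}
    result = {"binned": merged, "bin_means": {k: float(np.mean(v))
                                              for k, v in groups.items()}}
    if len(usable) >= 2:
        F, df1, df2, p = welch_anova(list(usable.values()))
        result["welch"] = {"F": F, "df1": df1, "df2": df2, "p": p}
        result["tukey"] = tukey_kramer(usable, alpha=alpha)
    return result


def coverage_fraction(profile: pd.DataFrame, events: pd.DataFrame,
                      prob_threshold: float = 0.8) -> float:
    """Fraction of high-probability sites with at least one observed cleavage.

    Among CSOs whose predicted probability is >= ``prob_threshold``, the
    fraction whose (substrate, P1') carries an observed event count >= 1.
    Returns NaN when no site reaches the threshold.
    """
    high = profile[profile["probability"] >= prob_threshold]
    if high.empty:
        return float("nan")
    observed = set(zip(events.loc[events["count"] >= 1, "substrate_id"],
                       events.loc[events["count"] >= 1, "p1prime"]))
    hits = sum((s, p) in observed
               for s, p in zip(high["substrate_id"], high["p1prime"]))
    return hits / len(high)


DEFAULT_LENGTH_WINDOWS = {"class_I": (8, 11), "class_II": (11, 20)}


def length_distribution(peptides, windows: dict[str, tuple[int, int]] | None = None,
                        by: list[str] | None = None) -> pd.DataFrame:
    """Per-condition peptide-length summary: mean length, fraction per window.

    The HLA class II window is fixed at 11-20 residues inclusive; the class
    I window defaults to 8-11 as a configurable convention.  Windows may
    overlap, in which case fractions are reported independently.
    """
    windows = windows or DEFAULT_LENGTH_WINDOWS
    df = _length_frame(peptides)
    by = by or [c for c in ("cathepsin", "time_h") if c in df.columns]
    iterator = df.groupby(by) if by else [((), df)]
    rows = []
    for key, grp in iterator:
        lengths = grp["length"].to_numpy()
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row["n"] = len(lengths)
        row["mean_length"] = float(lengths.mean())
        for name, (lo, hi) in windows.items():
            row[f"frac_{name}"] = float(((lengths >= lo) & (lengths <= hi)).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _length_frame(peptides) -> pd.DataFrame:
    if isinstance(peptides, pd.DataFrame):
        df = peptides.copy()
        if "length" not in df.columns:
            df["length"] = df["sequence"].str.len()
        return df
    return pd.DataFrame({"length": [len(p) for p in peptides]})


def distance_to_high_prob_site(events: pd.DataFrame, profile: pd.DataFrame,
                               threshold: float = 0.8) -> pd.DataFrame:
    """Signed offset from each observed cleavage to the nearest high-probability site.

    For every observed event the nearest predicted site with probability
    above ``threshold`` on the same substrate is found and the signed
    residue offset (event P1' minus site P1') reported; negative values
    mean the cut lies N-terminal of the predicted site, the direction in
    which a carboxypeptidase-shaved product shifts the distribution.  Ties
    resolve toward the N-terminal site.  Events on substrates without any
    high-probability site get NaN.
    """
    high = profile[profile["probability"] > threshold]
    sites = {sub: np.sort(grp["p1prime"].to_numpy())
             for sub, grp in high.groupby("substrate_id")}
    rows = []
    for row in events.itertuples():
        cand = sites.get(row.substrate_id)
        if cand is None or len(cand) == 0:
            dist = float("nan")
        else:
            offsets = row.p1prime - cand
            best = np.abs(offsets).min()
            ties = offsets[np.abs(offsets) == best]
            dist = float(ties.min())  # prefer the negative (N-terminal) side
        rows.append({"substrate_id": row.substrate_id,
                     "cathepsin": row.cathepsin, "p1prime": row.p1prime,
                     "count": row.count, "distance": dist})
    return pd.DataFrame(rows)


def cluster_samples(presence: pd.DataFrame, n_clusters: int | None = None) -> dict:
    """Ward-linkage clustering of samples over peptide incidence vectors.

    Samples (rows) are ordered lexicographically by id before linkage so
    the tree is deterministic; distances are Euclidean on the 0/1 incidence
    matrix.  Returns the scipy linkage matrix, the sample order, and (if
    ``n_clusters`` is given) flat cluster labels.
    """
    if presence.shape[0] < 2:
        raise ValueError("need >= 2 samples to cluster")
    presence = presence.sort_index()
    Z = hierarchy.linkage(presence.to_numpy(float), method="ward",
                          metric="euclidean")
    out = {"linkage": Z, "samples": list(presence.index)}
    if n_clusters is not None:
        out["flat"] = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return out
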