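"""Map MS-identified digest peptides to per-bond cleavage events.

Each detected peptide testifies to at most two hydrolysis events: one at
its amino terminus (unless it begins the substrate chain) and one at its
carboxy terminus (unless it ends the chain).  Events are indexed by P1',
the 1-based position of the first residue after the cut, so an internal
peptide spanning [start, end] yields events at P1' = start and
P1' = end + 1.  Counts are accumulated per (substrate, cathepsin,
incubation time, pH) condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

CONDITION_KEYS = ["substrate_id", "cathepsin", "time_h", "ph"]


@dataclass(frozen=True)
class PeptideObservation:
    """One MS-identified peptide assigned to a substrate span (1-based, inclusive)."""

    sequence: str
    substrate_id: str
    start: int
    end: int
    sample_id: str = "sample1"
    cathepsin: str = "unknown"
    time_h: float = 24.0
    ph: float = 6.0


def locate_peptide(substrate: str, peptide: str,
                   il_equivalent: bool = False) -> list[tuple[int, int]]:
    """All (possibly overlapping) occurrences of a peptide, 1-based spans.

    With ``il_equivalent`` the isobaric residues I and L are treated as
    interchangeable, as they are indistinguishable by standard MS/MS.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    hay, needle = substrate.upper(), peptide.upper()
    if il_equivalent:
        hay = hay.replace("I", "L")
        needle = needle.replace("I", "L")
    spans = []
    start = hay.find(needle)
    while start != -1:
        spans.append((start + 1, start + len(needle)))
        start = hay.find(needle, start + 1)
    return spans


def peptide_to_events(span: tuple[int, int], substrate_length: int) -> list[int]:
    """P1' positions of the 0-2 cleavage events implied by one peptide span.

    Chain termini are not cleavage products: a peptide abutting the
    N-terminus contributes no amino-end event, and likewise at the
    C-terminus.
    """
    start, end = span
    if not (1 <= start <= end <= substrate_length):
        raise ValueError(f"invalid span {span} for length {substrate_length}")
    events = []
    if start > 1:
        events.append(start)
    if end < substrate_length:
        events.append(end + 1)
    return events


def _observation_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations.copy()
    return pd.DataFrame([vars(o) if not isinstance(o, dict) else o
                         for o in observations])


def accumulate_events(observations, substrates: dict[str, str],
                      controls=None, drop_control_peptides: bool = True,
                      unique_per_condition: bool = True) -> pd.DataFrame:
    """Accumulate per-bond cleavage-event counts from peptide observations.

    Parameters
    ----------
    observations : DataFrame or iterable of PeptideObservation
        Columns sequence, substrate_id, start, end, sample_id, cathepsin,
        time_h, ph.
    substrates : dict
        substrate_id -> sequence; used for length, integrity checking and
        ambiguity marking.
    controls : optional
        No-enzyme control observations; peptides present in the control for
        the same substrate and time are excluded when
        ``drop_control_peptides`` is set.
    unique_per_condition : bool
        Count identical peptide sequences once within one
        (sample, substrate, time, pH) condition; across samples they add.

    Returns
    -------
    DataFrame with columns substrate_id, cathepsin, time_h, ph, p1prime,
    count, peptides (provenance: contributing sequences, ';'-joined).

    Raises
    ------
    ValueError if an observation's sequence does not match its claimed span.
    """
    df = _observation_frame(observations)
    if df.empty:
        return pd.DataFrame(columns=CONDITION_KEYS + ["p1prime", "count", "peptides"])

    for row in df.itertuples():
        sub = substrates.get(row.substrate_id)
        if sub is None:
            raise KeyError(f"unknown substrate {row.substrate_id!r}")
        claimed = sub[row.start - 1:row.end]
        if claimed != row.sequence.upper():
            raise ValueError(
                f"integrity error: peptide {row.sequence!r} does not match "
                f"{row.substrate_id}[{row.start}:{row.end}] = {claimed!r}")

    if controls is not None and drop_control_peptides:
        ctrl = _observation_frame(controls)
        if not ctrl.empty:
            ctrl_keys = set(zip(ctrl["substrate_id"], ctrl["sequence"].str.upper(),
                                ctrl["time_h"]))
            mask = [
                (r.substrate_id, r.sequence.upper(), r.time_h) not in ctrl_keys
                for r in df.itertuples()
            ]
            n_drop = len(df) - sum(mask)
            if n_drop:
                logger.info("excluding %d peptides present in negative controls", n_drop)
            df = df[mask]

    if unique_per_condition:
        df = df.drop_duplicates(
            subset=["sample_id", "substrate_id", "time_h", "ph", "sequence"])

    rows = []
    for row in df.itertuples():
        sub = substrates[row.substrate_id]
        ambiguous = len(locate_peptide(sub, row.sequence)) > 1
        for p1prime in peptide_to_events((row.start, row.end), len(sub)):
            rows.append({
                "substrate_id": row.substrate_id, "cathepsin": row.cathepsin,
                "time_h": row.time_h, "ph": row.ph, "p1prime": p1prime,
                "peptide": row.sequence, "ambiguous": ambiguous,
            })
    if not rows:
        return pd.DataFrame(columns=CONDITION_KEYS + ["p1prime", "count", "peptides"])

    ev = pd.DataFrame(rows)
    out = (ev.groupby(CONDITION_KEYS + ["p1prime"], as_index=False)
             .agg(count=("peptide", "size"),
                  peptides=("peptide", lambda s: ";".join(sorted(set(s)))),
                  ambiguous=("ambiguous", "any")))
    return out.sort_values(CONDITION_KEYS + ["p1prime"]).reset_index(drop=True)


def region_summary(events: pd.DataFrame,
                   regions: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Sum event counts per named region (1-based inclusive spans).

    Regions must not overlap.  Each event is attributed to the region whose
    span contains its P1'; events outside every region are reported under
    the reserved name ``(outside)``.
    """
    spans = sorted(regions.items(), key=lambda kv: kv[1])
    for (na, (sa, ea)), (nb, (sb, eb)) in zip(spans, spans[1:]):
        if sb <= ea:
            raise ValueError(f"regions {na!r} and {nb!r} overlap")

    def classify(p1prime: int) -> str:
        for name, (s, e) in spans:
            if s <= p1prime <= e:
                return name
        return "(outside)"

    ev = events.copy()
    ev["region"] = ev["p1prime"].map(classify)
    out = (ev.groupby(CONDITION_KEYS + ["region"], as_index=False)["count"].sum())
    return out.sort_values(CONDITION_KEYS + ["region"]).reset_index(drop=True)
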