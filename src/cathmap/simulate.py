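"""Synthetic ground truth: cleavage rules, training libraries, digests, Ig-like sequences.

Every analysis stage in this package can be exercised against data with a
known answer.  A :class:`GroundTruthRule` plays the role of a protease's
true specificity: each scissile dipeptide carries its own logistic model
over the 24 principal-component features of an octamer, so the planted
structure matches what the per-dipeptide ensembles are built to recover.
From a rule one can draw labeled peptide-library training sets, simulate
time-course digests with independent per-bond exponential cut hazards and
an instrument detection window that censors fragments outside 6-40
residues, and generate Ig-like records with family-structured frameworks
and a guaranteed CDR3-anchor cysteine.

Simulated digests come with a :class:`DigestLedger` recording exactly
which bonds were cut and which fragments were detectable — the ground
truth for round-trip tests.  Analyses must reach observations only through
the public peptide table, never through the ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .digest import PeptideObservation  # noqa: F401  (re-exported convenience)
from .encoding import OctamerEncoder, enumerate_csos
from .ighv import IghvRecord
from .predictor import LabeledOctamer

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: study conditions for the simulated digests: detection window of the
#: nLC-MS instrument (residues) and the incubation time points (hours)
DEFAULT_DETECTION_WINDOW = (6, 40)
DEFAULT_TIME_POINTS = (6.0, 24.0, 30.0)


class GroundTruthRule:
    """Planted cleavage specificity: one logistic model per scissile dipeptide.

    The probability that the bond inside octamer ``x`` (24 encoded values)
    with dipeptide ``d`` is cleavable is ``sigmoid(intercept_d + w_d . x)``.
    Dipeptide intercepts vary around the logit of a base rate, giving the
    between-dipeptide preference structure proteases show; a ``sparsity``
    fraction of dipeptides additionally carry context weights, standing in
    for flanking-position (P4..P4') effects.
    """

    def __init__(self, intercepts: dict[str, float],
                 weights: dict[str, np.ndarray], seed: int):
        self.intercepts = intercepts
        self.weights = weights
        self.seed = seed
        self._encoder = OctamerEncoder().fit()

    def octamer_probability(self, octamers) -> np.ndarray:
        """True cleavability probability for each 8-mer string."""
        octamers = list(octamers)
        if not octamers:
            return np.empty(0)
        X = self._encoder.transform(octamers)
        z = np.empty(len(octamers))
        for i, octamer in enumerate(octamers):
            d = octamer[3:5]
            z[i] = self.intercepts[d] + float(self.weights[d] @ X[i])
        return expit(z)

    def bond_probabilities(self, sequence: str,
                           substrate_id: str = "substrate") -> pd.DataFrame:
        """True per-bond probabilities for every full-window bond of a substrate."""
        csos = enumerate_csos(sequence, substrate_id)
        probs = self.octamer_probability([c.residues for c in csos])
        return pd.DataFrame({
            "substrate_id": substrate_id,
            "p1prime": [c.p1prime for c in csos],
            "octamer": [c.residues for c in csos],
            "probability": probs,
        })


def make_rule(seed: int = 0, sparsity: float = 0.25, effect_scale: float = 0.06,
              base_rate: float = 0.15, intercept_sd: float = 1.5) -> GroundTruthRule:
    """Draw a reproducible ground-truth rule.

    Parameters
    ----------
    sparsity : fraction of dipeptides carrying non-trivial context weights.
    effect_scale : SD of each of the 24 context weights where present.
    base_rate : marginal cleavage propensity around which dipeptide
        intercepts scatter (on the logit scale).
    intercept_sd : SD of dipeptide intercepts on the logit scale.
    """
    rng = np.random.RandomState(seed)
    base_logit = float(np.log(base_rate / (1.0 - base_rate)))
    dipeptides = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
    intercepts, weights = {}, {}
    for d in dipeptides:
        intercepts[d] = base_logit + intercept_sd * rng.randn()
        if rng.rand() < sparsity:
            weights[d] = effect_scale * rng.randn(24)
        else:
            weights[d] = np.zeros(24)
    return GroundTruthRule(intercepts, weights, seed)


def random_proteins(n: int, length: int, seed: int,
                    prefix: str = "prot") -> dict[str, str]:
    """Random substrates with uniform residue composition."""
    rng = np.random.RandomState(seed)
    letters = np.array(list(AMINO_ACIDS))
    return {f"{prefix}{i:03d}": "".join(rng.choice(letters, size=length))
            for i in range(n)}


def generate_training_library(rule: GroundTruthRule, n_proteins: int = 50,
                              protein_length: int = 300, seed: int = 0):
    """Labeled octamers drawn from a rule over random library proteins.

    Every full-window bond of every protein becomes one example, labeled
    cleaved with its true rule probability.  Returns
    ``(examples, truth, proteins)`` where ``truth`` retains the underlying
    probabilities for parameter-recovery tests.
    """
    if protein_length < 8:
        raise ValueError("protein_length must be >= 8")
    proteins = random_proteins(n_proteins, protein_length, seed)
    rng = np.random.RandomState(seed + 1)
    examples, truth_rows = [], []
    for sub_id in sorted(proteins):
        seq = proteins[sub_id]
        csos = enumerate_csos(seq, sub_id)
        probs = rule.octamer_probability([c.residues for c in csos])
        labels = (rng.rand(len(csos)) < probs).astype(int)
        for cso, p, lab in zip(csos, probs, labels):
            examples.append(LabeledOctamer(cso=cso, label=int(lab),
                                           source_id=sub_id))
            truth_rows.append({"substrate_id": sub_id, "p1prime": cso.p1prime,
                               "octamer": cso.residues,
                               "true_probability": float(p), "label": int(lab)})
    return examples, pd.DataFrame(truth_rows), proteins


@dataclass
class SyntheticDigestConfig:
    """Study conditions for a simulated time-course digest."""

    substrates: dict[str, str] | None = None
    n_substrates: int = 4
    substrate_length: int = 200
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    hazard_scale: float = 0.02           # per-hour rate multiplier on p_bond
    detection_window: tuple[int, int] = DEFAULT_DETECTION_WINDOW
    replicates: int = 2
    cathepsin: str = "synthetic"
    ph: float = 6.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.detection_window
        if lo < 1 or lo > hi:
            raise ValueError("detection window must satisfy 1 <= min <= max")
        tp = tuple(self.time_points)
        if any(t <= 0 for t in tp) or list(tp) != sorted(tp):
            raise ValueError("time points must be positive and increasing")


@dataclass
class DigestLedger:
    """Ground truth of a simulated digest, keyed by (replicate, substrate).

    ``cut_times`` maps each bond's P1' to the time it was cut (only bonds
    cut within the last time point appear); ``by_time`` records, per time
    point, the realized cut set, the fragment tiling and which fragments
    pass the detection window.
    """

    cut_times: dict = field(default_factory=dict)
    by_time: dict = field(default_factory=dict)

    def cuts_at(self, sample_id: str, substrate_id: str, t: float) -> set[int]:
        return set(self.by_time[(sample_id, substrate_id)][t]["cuts"])

    def to_json(self) -> dict:
        return {
            "cut_times": {f"{k[0]}|{k[1]}": {str(p): t for p, t in v.items()}
                          for k, v in self.cut_times.items()},
            "by_time": {f"{k[0]}|{k[1]}": {str(t): v2
                                           for t, v2 in v.items()}
                        for k, v in self.by_time.items()},
        }


def _fragments(length: int, cuts: list[int]) -> list[tuple[int, int]]:
    """Maximal uncut stretches (1-based inclusive spans) tiling the chain."""
    bounds = [1] + sorted(cuts) + [length + 1]
    return [(bounds[i], bounds[i + 1] - 1) for i in range(len(bounds) - 1)]


def simulate_digest(config: SyntheticDigestConfig,
                    rule: GroundTruthRule) -> tuple[pd.DataFrame, DigestLedger]:
    """Simulate a time-course in vitro digest under a planted rule.

    Each full-window bond carries an independent exponential cut hazard
    ``hazard_scale * p_bond`` per hour, so the bond is cut by time ``t``
    with probability ``1 - exp(-hazard_scale * p_bond * t)`` and the cut
    sets are nested across the time course.  At each time point the
    substrate decomposes into maximal uncut fragments; the detected peptide
    table contains exactly the fragments whose length falls inside the
    detection window.  Released fragments are not re-cut beyond the bond
    set (single-pass model).

    ``rule`` is either a :class:`GroundTruthRule` (full-window bonds only;
    bonds too close to the termini for an octamer are never cut) or any
    callable ``(sequence, substrate_id) -> DataFrame`` with columns
    ``p1prime`` and ``probability`` over the bonds of its choice.
    """
    substrates = config.substrates or random_proteins(
        config.n_substrates, config.substrate_length, config.seed + 500,
        prefix="sub")
    rng = np.random.RandomState(config.seed)
    lo, hi = config.detection_window
    rows = []
    ledger = DigestLedger()
    for r in range(config.replicates):
        sample_id = f"rep{r + 1}"
        for sub_id in sorted(substrates):
            seq = substrates[sub_id]
            if hasattr(rule, "bond_probabilities"):
                truth = rule.bond_probabilities(seq, sub_id)
            else:
                truth = rule(seq, sub_id)
            p = truth["probability"].to_numpy()
            positions = truth["p1prime"].to_numpy()
            rate = config.hazard_scale * p
            with np.errstate(divide="ignore"):
                cut_time = np.where(rate > 0,
                                    rng.exponential(1.0, size=len(p)) /
                                    np.where(rate > 0, rate, 1.0),
                                    np.inf)
            t_max = max(config.time_points)
            ledger.cut_times[(sample_id, sub_id)] = {
                int(pos): float(t) for pos, t in zip(positions, cut_time)
                if t <= t_max}
            ledger.by_time[(sample_id, sub_id)] = {}
            for t in config.time_points:
                cuts = [int(pos) for pos, ct in zip(positions, cut_time)
                        if ct <= t]
                frags = _fragments(len(seq), cuts)
                detected = [(s, e) for s, e in frags if lo <= e - s + 1 <= hi]
                ledger.by_time[(sample_id, sub_id)][t] = {
                    "cuts": cuts,
                    "fragments": [list(f) for f in frags],
                    "detected": [list(f) for f in detected],
                }
                for s, e in detected:
                    rows.append({
                        "sequence": seq[s - 1:e], "substrate_id": sub_id,
                        "start": s, "end": e, "sample_id": sample_id,
                        "cathepsin": config.cathepsin, "time_h": float(t),
                        "ph": config.ph,
                    })
    columns = ["sequence", "substrate_id", "start", "end", "sample_id",
               "cathepsin", "time_h", "ph"]
    peptides = pd.DataFrame(rows, columns=columns)
    peptides.attrs["substrates"] = substrates
    return peptides, ledger


# -- Ig-like sequences -------------------------------------------------------

_FR4 = "WGQGTLVTVSS"


def generate_synthetic_igs(n: int = 12, families: tuple[str, ...] = ("IGHV1", "IGHV3", "IGHV4"),
                           seed: int = 0, cdr3_length: int = 12) -> list[IghvRecord]:
    """Ig-like variable-region records with family-structured frameworks.

    Each family gets fixed framework segments (drawn once from the family
    name and ``seed``), shared by all its members; CDR1/2/3 loops are
    randomized per record.  The residue preceding CDR3 is a cysteine and is
    annotated as ``cdr3_cys``, mimicking the conserved anchor used for
    relative coordinates.  Labelled synthetic throughout — these are not
    germline IGHV sequences.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    letters = np.array(list(AMINO_ACIDS.replace("C", "")))  # no stray cysteines

    def segment(rng, length):
        return "".join(rng.choice(letters, size=length))

    frameworks = {}
    for fi, fam in enumerate(families):
        fam_rng = np.random.RandomState((seed * 131 + fi * 7 + 11) % (2**31 - 1))
        frameworks[fam] = (segment(fam_rng, 25), segment(fam_rng, 14),
                           segment(fam_rng, 30))
    rng = np.random.RandomState(seed + 1)
    records = []
    for i in range(n):
        fam = families[i % len(families)]
        fr1, fr2, fr3 = frameworks[fam]
        cdr1, cdr2 = segment(rng, 8), segment(rng, 7)
        cdr3 = segment(rng, cdr3_length)
        prefix = fr1 + cdr1 + fr2 + cdr2 + fr3
        sequence = prefix + "C" + cdr3 + _FR4
        records.append(IghvRecord(id=f"synthIg{i:03d}", sequence=sequence,
                                  family=fam, cdr3_cys=len(prefix) + 1))
    return records


def ig_annotation_table(records: list[IghvRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"id": r.id, "family": r.family,
                          "cdr3_cys": r.cdr3_cys} for r in records])
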