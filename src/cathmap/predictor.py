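"""Per-scissile-dipeptide neural-network ensembles for cleavage prediction.

Substrate specificity of a protease depends strongly on the P1-P1' pair at
the scissile bond, so training examples are partitioned by that dipeptide
(up to 400 partitions) and an independent ensemble of small feed-forward
networks is fitted per partition.  Each network maps the 24
principal-component features of an octamer to a cleavage probability in
[0, 1]; the ensemble prediction is the arithmetic mean of its members.
Partitions with too few examples of either class fall back to a
Laplace-smoothed constant rate, and bonds whose dipeptide was never seen
in training receive the global positive prevalence, flagged as fallback.

Trained model sets serialize to portable JSON (weights, configuration,
property-table hash, seeds); prediction from a serialized model uses an
explicit tanh/logistic forward pass, verified against the fitted sklearn
networks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier

from .digest import locate_peptide, peptide_to_events, _observation_frame
from .encoding import CleavageSiteOctamer, OctamerEncoder, enumerate_csos

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabeledOctamer:
    """A training example: one octamer window labeled cleaved (1) or not (0)."""

    cso: CleavageSiteOctamer
    label: int
    source_id: str = ""

    @property
    def dipeptide(self) -> str:
        return self.cso.dipeptide


def build_library_labels(peptides, library_proteins: dict[str, str],
                         il_equivalent: bool = False) -> list[LabeledOctamer]:
    """Construct labeled octamers from a peptide-library digest.

    Positive examples are octamers whose scissile bond coincides with an
    observed peptide terminus interior to a protein (the bond was cut);
    negative examples are octamers at bonds strictly interior to an
    observed peptide (the bond survived in that product).  A bond observed
    both cut and interior is labeled positive: a single observed cut proves
    cleavability.  Peptides that cannot be located in any library protein
    are logged and skipped.
    """
    df = _observation_frame(peptides)
    positives: dict[tuple[str, int], str] = {}
    negatives: dict[tuple[str, int], str] = {}
    for row in df.itertuples():
        protein = library_proteins.get(row.substrate_id)
        spans = []
        if protein is not None:
            spans = locate_peptide(protein, row.sequence, il_equivalent)
            if not spans and 1 <= row.start <= row.end <= len(protein) \
                    and protein[row.start - 1:row.end] == row.sequence.upper():
                spans = [(row.start, row.end)]
        if not spans:
            logger.info("unmappable peptide %r skipped", row.sequence)
            continue
        source = getattr(row, "sample_id", "")
        for start, end in spans:
            # cut bonds at the peptide termini (chain termini excluded)
            for p1prime in peptide_to_events((start, end), len(protein)):
                positives[(row.substrate_id, p1prime - 1)] = source
            # surviving bonds strictly interior to the product
            for p1 in range(start, end):
                negatives.setdefault((row.substrate_id, p1), source)

    labeled = []
    for key_map, label in ((positives, 1), (negatives, 0)):
        for (sub_id, p1), source in key_map.items():
            if label == 0 and (sub_id, p1) in positives:
                continue  # conflict: an observed cut proves cleavability
            protein = library_proteins[sub_id]
            if not 4 <= p1 <= len(protein) - 4:
                continue  # truncated window
            window = protein[p1 - 4:p1 + 4]
            try:
                cso = CleavageSiteOctamer(sub_id, p1, window)
            except ValueError:
                continue
            labeled.append(LabeledOctamer(cso=cso, label=label, source_id=source))
    labeled.sort(key=lambda ex: (ex.cso.substrate_id, ex.cso.scissile_p1, -ex.label))
    return labeled


def partition_by_dipeptide(data: list[LabeledOctamer]) -> dict[str, list[LabeledOctamer]]:
    """Group examples by their P1P1' scissile dipeptide (each in exactly one)."""
    parts: dict[str, list[LabeledOctamer]] = {}
    for ex in data:
        parts.setdefault(ex.dipeptide, []).append(ex)
    return parts


def _dipeptide_seed(base: int, dipeptide: str, member: int = 0) -> int:
    """Stable sub-seed per (dipeptide, member), independent of dict order."""
    h = (ord(dipeptide[0]) * 131 + ord(dipeptide[1])) * 1009 + member
    return int((base * 7919 + h) % (2**31 - 1))


def _forward(member: dict, X: np.ndarray) -> np.ndarray:
    """tanh-hidden / logistic-output forward pass from serialized weights."""
    W1 = np.asarray(member["W1"])
    b1 = np.asarray(member["b1"])
    W2 = np.asarray(member["W2"])
    b2 = float(member["b2"])
    hidden = np.tanh(X @ W1 + b1)
    z = hidden @ W2 + b2
    return 1.0 / (1.0 + np.exp(-z))


class DipeptideEnsembleClassifier(ClassifierMixin, BaseEstimator):
    """Cleavage classifier: one neural-net ensemble per scissile dipeptide.

    Parameters
    ----------
    encoder : OctamerEncoder or None
        Feature encoder; None uses the bundled default property table with
        3 principal components.
    n_members : int, default 10
        Networks per ensemble, each trained on a stratified bootstrap
        resample with its own seed.
    hidden_units : int, default 6
        tanh units in the single hidden layer.
    alpha : float, default 5.0
        L2 penalty on the network weights.  Per-dipeptide partitions are
        small (tens of binary examples for 24 inputs), so heavy shrinkage
        is what keeps ensemble outputs calibrated across dipeptides.
    max_iter, tol
        Full-batch (lbfgs) convergence controls.
    min_examples : int, default 10
        Minimum examples of each class a partition needs for network
        training; below this a Laplace-smoothed constant-rate model is used.
    max_negative_ratio : float, default 5.0
        Negatives are down-sampled (seeded) to at most this multiple of the
        positives in each partition, since surviving bonds vastly outnumber
        cut bonds in library digests.
    random_state : int, default 0

    Attributes
    ----------
    encoder_ : fitted OctamerEncoder
    ensembles_ : dict  dipeptide -> serializable model entry
    fallback_rate_ : float  global smoothed positive prevalence
    classes_ : ndarray([0, 1])
    """

    def __init__(self, encoder: OctamerEncoder | None = None, n_members: int = 10,
                 hidden_units: int = 6, alpha: float = 5.0, max_iter: int = 5000,
                 tol: float = 1e-6, min_examples: int = 10,
                 max_negative_ratio: float = 5.0, random_state: int = 0,
                 cathepsin: str = "unknown"):
        self.encoder = encoder
        self.n_members = n_members
        self.hidden_units = hidden_units
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol
        self.min_examples = min_examples
        self.max_negative_ratio = max_negative_ratio
        self.random_state = random_state
        self.cathepsin = cathepsin

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _octamer_strings(X) -> list[str]:
        out = []
        for x in X:
            if isinstance(x, LabeledOctamer):
                out.append(x.cso.residues)
            elif isinstance(x, CleavageSiteOctamer):
                out.append(x.residues)
            else:
                out.append(str(x).upper())
        return out

    def _train_member(self, Xp: np.ndarray, y: np.ndarray, seed: int) -> dict:
        rng = np.random.RandomState(seed)
        idx = []
        for cls in (0, 1):  # stratified bootstrap keeps both classes present
            cls_idx = np.flatnonzero(y == cls)
            idx.append(rng.choice(cls_idx, size=len(cls_idx), replace=True))
        idx = np.concatenate(idx)
        net = MLPClassifier(hidden_layer_sizes=(self.hidden_units,),
                            activation="tanh", solver="lbfgs", alpha=self.alpha,
                            max_iter=self.max_iter, tol=self.tol,
                            random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lbfgs may stop at max_iter
            net.fit(Xp[idx], y[idx])
        return {
            "W1": net.coefs_[0].tolist(), "b1": net.intercepts_[0].tolist(),
            "W2": net.coefs_[1].ravel().tolist(),
            "b2": float(net.intercepts_[1][0]), "seed": seed,
        }

    def _fit_partition(self, dipeptide: str, Xp: np.ndarray,
                       yp: np.ndarray) -> dict:
        n_pos = int(yp.sum())
        n_neg = int(len(yp) - n_pos)
        if min(n_pos, n_neg) < self.min_examples:
            # rate from the full partition, before any down-sampling
            rate = (n_pos + 1.0) / (n_pos + n_neg + 2.0)  # Laplace smoothing
            return {"kind": "constant", "rate": rate,
                    "degenerate": min(n_pos, n_neg) == 0,
                    "n_pos": n_pos, "n_neg": n_neg}
        cap = int(np.ceil(self.max_negative_ratio * n_pos))
        neg_factor = 1.0
        if n_neg > cap:
            rng = np.random.RandomState(_dipeptide_seed(self.random_state,
                                                        dipeptide, 9999))
            neg_idx = np.flatnonzero(yp == 0)
            keep_neg = rng.choice(neg_idx, size=cap, replace=False)
            keep = np.sort(np.concatenate([np.flatnonzero(yp == 1), keep_neg]))
            Xp, yp = Xp[keep], yp[keep]
            neg_factor = cap / n_neg  # undo the prior shift at prediction time
        members = [
            self._train_member(Xp, yp,
                               _dipeptide_seed(self.random_state, dipeptide, m))
            for m in range(self.n_members)
        ]
        return {"kind": "ensemble", "members": members,
                "neg_factor": neg_factor, "n_pos": n_pos, "n_neg": n_neg}

    # -- sklearn API -----------------------------------------------------

    def fit(self, X, y):
        """Fit per-dipeptide ensembles on octamers ``X`` with binary labels ``y``."""
        octamers = self._octamer_strings(X)
        y = np.asarray(y, dtype=int)
        if octamers and set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        self.encoder_ = clone(self.encoder) if self.encoder is not None \
            else OctamerEncoder()
        self.encoder_.fit()
        self.classes_ = np.array([0, 1])
        feats = self.encoder_.transform(octamers) if octamers \
            else np.empty((0, 24))

        groups: dict[str, list[int]] = {}
        for i, octamer in enumerate(octamers):
            groups.setdefault(octamer[3:5], []).append(i)

        self.ensembles_ = {}
        for dipeptide in sorted(groups):
            idx = np.array(groups[dipeptide])
            self.ensembles_[dipeptide] = self._fit_partition(
                dipeptide, feats[idx], y[idx])

        n_pos = int(y.sum())
        self.fallback_rate_ = (n_pos + 1.0) / (len(y) + 2.0)
        self.n_features_in_ = 8
        return self

    def _proba_one(self, dipeptide: str, feat: np.ndarray) -> tuple[float, bool]:
        entry = self.ensembles_.get(dipeptide)
        if entry is None:
            return float(self.fallback_rate_), True
        if entry["kind"] == "constant":
            return float(entry["rate"]), False
        p = np.mean([_forward(m, feat[None, :])[0] for m in entry["members"]])
        factor = entry.get("neg_factor", 1.0)
        if factor < 1.0:  # negatives were down-sampled: rescale the odds back
            p = np.clip(p, 1e-12, 1.0 - 1e-12)
            odds = factor * p / (1.0 - p)
            p = odds / (1.0 + odds)
        return float(p), False

    def predict_detail(self, X) -> pd.DataFrame:
        """Per-octamer probability with dipeptide key and fallback flag."""
        octamers = self._octamer_strings(X)
        feats = self.encoder_.transform(octamers) if octamers \
            else np.empty((0, 24))
        rows = []
        for octamer, feat in zip(octamers, feats):
            p, flagged = self._proba_one(octamer[3:5], feat)
            rows.append({"octamer": octamer, "dipeptide": octamer[3:5],
                         "probability": p, "fallback": flagged})
        return pd.DataFrame(rows, columns=["octamer", "dipeptide",
                                           "probability", "fallback"])

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_detail(X)["probability"].to_numpy()
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_profile(self, sequence: str,
                        substrate_id: str = "substrate") -> pd.DataFrame:
        """Cleavage-probability profile over every full octamer of a substrate.

        Returns a tidy frame with one row per scissile bond: substrate_id,
        p1prime (first residue after the cut), probability, dipeptide,
        fallback flag and cathepsin.
        """
        csos = enumerate_csos(sequence, substrate_id)
        detail = self.predict_detail(csos)
        detail.insert(0, "substrate_id", substrate_id)
        detail.insert(1, "p1prime", [c.p1prime for c in csos])
        detail["cathepsin"] = self.cathepsin
        return detail

    # -- serialization ---------------------------------------------------

    def to_json(self) -> dict:
        """Portable model-set representation (weights, config, provenance)."""
        return {
            "format": "cathmap-dipeptide-model/1",
            "cathepsin": self.cathepsin,
            "config": {k: getattr(self, k) for k in
                       ("n_members", "hidden_units", "alpha", "max_iter",
                        "tol", "min_examples", "max_negative_ratio",
                        "random_state")},
            "encoding_hash": self.encoder_.table_hash_,
            "fallback_rate": self.fallback_rate_,
            "ensembles": self.ensembles_,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh)

    @classmethod
    def from_json(cls, payload: dict,
                  encoder: OctamerEncoder | None = None) -> "DipeptideEnsembleClassifier":
        model = cls(encoder=encoder, cathepsin=payload.get("cathepsin", "unknown"),
                    **payload["config"])
        model.encoder_ = clone(model.encoder) if model.encoder is not None \
            else OctamerEncoder()
        model.encoder_.fit()
        if model.encoder_.table_hash_ != payload["encoding_hash"]:
            raise ValueError(
                "encoding mismatch: model was trained with property table "
                f"{payload['encoding_hash']}, current encoder is "
                f"{model.encoder_.table_hash_}")
        model.classes_ = np.array([0, 1])
        model.fallback_rate_ = float(payload["fallback_rate"])
        model.ensembles_ = payload["ensembles"]
        model.n_features_in_ = 8
        return model

    @classmethod
    def load(cls, path, encoder: OctamerEncoder | None = None):
        with open(path) as fh:
            return cls.from_json(json.load(fh), encoder=encoder)


def train_ensemble(partition: list[LabeledOctamer], **params) -> dict:
    """Fit one dipeptide partition; returns the serializable ensemble entry.

    Thin wrapper over :class:`DipeptideEnsembleClassifier` for a single
    partition; all examples must share one scissile dipeptide.
    """
    dipeptides = {ex.dipeptide for ex in partition}
    if len(dipeptides) != 1:
        raise ValueError(f"partition mixes dipeptides: {sorted(dipeptides)}")
    model = DipeptideEnsembleClassifier(**params)
    model.fit(partition, [ex.label for ex in partition])
    return model.ensembles_[dipeptides.pop()]


def predict_profile(sequence: str, model: DipeptideEnsembleClassifier,
                    substrate_id: str = "substrate") -> pd.DataFrame:
    """Module-level convenience wrapper over ``model.predict_profile``."""
    return model.predict_profile(sequence, substrate_id)


def cross_validate(data: list[LabeledOctamer], folds: int = 5,
                   threshold: float = 0.5, seed: int = 0,
                   **model_params) -> pd.DataFrame:
    """Stratified k-fold cross-validation of the dipeptide-ensemble model.

    Folds are stratified by label within each dipeptide partition so every
    fold sees the same class balance per dipeptide that training does.
    Returns per-fold and pooled rows with TPR and FPR at ``threshold`` and
    AUROC over held-out predictions only.  Folds whose held-out set lacks a
    class are skipped with a warning (their AUROC is undefined).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.RandomState(seed)
    fold_of = np.empty(len(data), dtype=int)
    parts: dict[tuple[str, int], list[int]] = {}
    for i, ex in enumerate(data):
        parts.setdefault((ex.dipeptide, ex.label), []).append(i)
    for key in sorted(parts):
        idx = np.array(parts[key])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            fold_of[i] = j % folds

    rows, pooled_y, pooled_p = [], [], []
    for f in range(folds):
        train = [ex for ex, g in zip(data, fold_of) if g != f]
        test = [ex for ex, g in zip(data, fold_of) if g == f]
        y_test = np.array([ex.label for ex in test])
        if len(test) == 0 or len(np.unique(y_test)) < 2:
            warnings.warn(f"fold {f} lacks a class; skipped")
            continue
        model = DipeptideEnsembleClassifier(random_state=seed * 1000 + f,
                                            **model_params)
        model.fit(train, [ex.label for ex in train])
        p = model.predict_proba(test)[:, 1]
        pooled_y.append(y_test)
        pooled_p.append(p)
        rows.append(_metric_row(f"fold{f}", y_test, p, threshold))
    if pooled_y:
        rows.append(_metric_row("pooled", np.concatenate(pooled_y),
                                np.concatenate(pooled_p), threshold))
    return pd.DataFrame(rows)


def _metric_row(name: str, y: np.ndarray, p: np.ndarray,
                threshold: float) -> dict:
    pred = p >= threshold
    pos, neg = y == 1, y == 0
    return {
        "fold": name, "n": len(y),
        "tpr": float(pred[pos].mean()) if pos.any() else np.nan,
        "fpr": float(pred[neg].mean()) if neg.any() else np.nan,
        "auroc": float(roc_auc_score(y, p)),
    }
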