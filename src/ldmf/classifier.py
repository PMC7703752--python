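"""SVM training, multi-round active learning and leave-one-out evaluation.

Training rebuilds the six positive-set PWMs, z-standardizes the
36-dimensional feature vectors and fits an RBF-kernel support vector
machine with class weights inversely proportional to class frequency
(the negative pool is orders of magnitude larger than the positive set,
so unweighted training would collapse to the majority class).

The active-learning protocol runs three rounds:

1. positives = the known motif set, negatives drawn at random from the
   proteome's candidate windows;
2. negatives are augmented with *hard negatives* mined from a decoy pool
   — candidates the round-1 model scores in its top decile yet that are
   labelled negative (pattern-true sites in the wrong structural
   context);
3. positives are augmented with externally validated hits.

Evaluation is leave-one-out over the positive set: each positive is held
out, the model retrained, and the held-out site scored. Negatives enter
the confusion matrix through k-fold models (default 10) trained with all
positives, so every negative is also scored out-of-fold. A pure
leave-one-sample-out variant is available for small sets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from ldmf.features import (
    AA_ALPHABET,
    LAYOUT_VERSION,
    N_FEATURES,
    PWM_FEATURE_ORDER,
    SS_ALPHABET,
    Pwm,
    build_pwm,
    featurize_many,
    make_background,
    uniform_ss_background,
)
from ldmf.io_formats import LdmfError, PropertyTable, ProteinRecord
from ldmf.sspred import default_propensity_model, predict_ss
from ldmf.windows import WindowInstance, attach_ss, enumerate_candidates

log = logging.getLogger(__name__)

PROVENANCE_TAGS = ("known", "ortholog", "experimental", "random_negative", "hard_negative")


@dataclass(frozen=True)
class TrainConfig:
    """Every tunable of training, evaluation and active learning."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float = 1.0 / N_FEATURES
    class_weight: str = "balanced"
    pseudocount: float = 1.0
    #: score each training positive with PWMs built from the *other*
    #: positives, so training-time features match what an unseen motif
    #: sees at scan time (in-sample PWM scores are optimistically shifted)
    jackknife_positive_features: bool = True
    seed: int = 0
    loocv_scheme: str = "hybrid"  # or "loo_all"
    n_negative_folds: int = 10
    n_random_negatives: int = 2000
    hard_negative_quantile: float = 0.90
    n_rounds: int = 3


@dataclass(frozen=True)
class TrainingSet:
    positives: tuple[WindowInstance, ...]
    negatives: tuple[WindowInstance, ...]
    #: source tag per window key, e.g. known / hard_negative
    provenance: Mapping[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "positives", tuple(self.positives))
        object.__setattr__(self, "negatives", tuple(self.negatives))
        if len(self.positives) < 2:
            raise LdmfError("training requires at least 2 positives")
        pos_keys = {w.key for w in self.positives}
        neg_keys = {w.key for w in self.negatives}
        clash = pos_keys & neg_keys
        if clash:
            raise LdmfError(f"windows in both classes: {sorted(clash)[:5]}")


@dataclass
class EvalMetrics:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / total if total else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


@dataclass(frozen=True)
class ModelBundle:
    """Everything needed to reproduce decision scores, in plain arrays."""

    pwms: Mapping[tuple[str, str], Pwm]
    tables: Mapping[str, PropertyTable]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    C: float
    kernel: str
    layout_version: str = LAYOUT_VERSION
    round: int = 1
    training_hashes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.round not in (1, 2, 3):
            raise ValueError("round must be 1, 2 or 3")
        if self.kernel != "rbf":
            raise ValueError("only the rbf kernel is persisted/replayed")

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        """Signed SVM margin for raw (unstandardized) feature rows."""
        X = np.atleast_2d(features)
        if X.shape[1] != len(self.scaler_mean):
            raise LdmfError("feature layout mismatch")
        Z = (X - self.scaler_mean) / self.scaler_scale
        sq = (
            np.sum(Z**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(sq, 0.0))
        return K @ self.dual_coef + self.intercept

    def featurize_windows(self, windows: Sequence[WindowInstance]) -> np.ndarray:
        return featurize_many(windows, self.pwms, self.tables)


def _hash_windows(windows: Iterable[WindowInstance]) -> str:
    h = hashlib.sha256()
    for w in sorted(windows, key=lambda w: w.key):
        h.update(f"{w.protein_id}\t{w.anchor}\t{w.core}\t{w.label}\n".encode())
    return h.hexdigest()


def _empirical_ss_background(negatives: Sequence[WindowInstance]) -> np.ndarray:
    counts = {"H": 0, "E": 0, "C": 0}
    for w in negatives:
        for seg in (w.ss_core, w.ss_upstream, w.ss_downstream):
            if seg is None:
                continue
            for c in seg:
                if c in counts:
                    counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        return uniform_ss_background()
    # shrink toward uniform: a state that is merely rare in the negatives
    # must not make every occurrence look like motif evidence
    # (log-odds vs a near-zero background blows up)
    lam = 0.25
    freqs = {k: (1 - lam) * v / total + lam / 3 for k, v in counts.items()}
    return make_background(freqs, alphabet=SS_ALPHABET)


def build_model_pwms(
    positives: Sequence[WindowInstance],
    pseudocount: float = 1.0,
    seq_background: Mapping[str, float] | None = None,
    ss_background: np.ndarray | None = None,
) -> dict[tuple[str, str], Pwm]:
    """The six positive-set PWMs: {sequence, ss} x {core, upstream, downstream}."""
    if seq_background is None:
        from ldmf.resources import load_background_composition

        seq_bg = make_background(load_background_composition(), AA_ALPHABET)
    else:
        seq_bg = make_background(seq_background, AA_ALPHABET)
    if ss_background is None:
        ss_background = uniform_ss_background()
    pwms = {}
    for kind, region in PWM_FEATURE_ORDER:
        bg = seq_bg if kind == "sequence" else ss_background
        pwms[(kind, region)] = build_pwm(
            positives,
            region=region,
            alphabet_kind=kind,
            pseudocount=pseudocount,
            background=bg,
        )
    return pwms


def train(
    ts: TrainingSet,
    config: TrainConfig = TrainConfig(),
    tables: Mapping[str, PropertyTable] | None = None,
    round: int = 1,
) -> ModelBundle:
    """Fit PWMs (positives only), the scaler and the SVM; return the bundle."""
    if tables is None:
        from ldmf.resources import load_property_tables

        tables = load_property_tables()
    if not ts.negatives:
        raise LdmfError("degenerate single-class training set")
    for w in list(ts.positives) + list(ts.negatives):
        if not w.has_ss:
            raise LdmfError(f"attach_ss first: {w.key} has no SS annotation")

    ss_bg = _empirical_ss_background(ts.negatives)
    pwms = build_model_pwms(
        ts.positives, pseudocount=config.pseudocount, ss_background=ss_bg
    )

    X_pos_full = featurize_many(ts.positives, pwms, tables)
    if config.jackknife_positive_features and len(ts.positives) > 2:
        rows = []
        for i, w in enumerate(ts.positives):
            others = [p for j, p in enumerate(ts.positives) if j != i]
            loo_pwms = build_model_pwms(
                others, pseudocount=config.pseudocount, ss_background=ss_bg
            )
            rows.append(featurize_many([w], loo_pwms, tables)[0])
        X_pos = np.vstack(rows)
    else:
        X_pos = X_pos_full
    X_neg = featurize_many(ts.negatives, pwms, tables)
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(X_pos)), -np.ones(len(X_neg))])

    # the scaler is fitted on deployment-consistent features (full PWMs for
    # everyone): a feature that is constant at deployment must not acquire
    # phantom variance from the jackknife offset
    X_deploy = np.vstack([X_pos_full, X_neg])
    mean = X_deploy.mean(axis=0)
    scale = X_deploy.std(axis=0)
    scale[scale < 1e-9] = 1.0
    Z = (X - mean) / scale

    svc = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma,
        class_weight=config.class_weight,
        random_state=config.seed,
    )
    svc.fit(Z, y)
    # sklearn orders classes_ as [-1, +1]; decision_function > 0 => positive
    bundle = ModelBundle(
        pwms=pwms,
        tables=tables,
        scaler_mean=mean,
        scaler_scale=scale,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        gamma=float(config.gamma),
        C=config.C,
        kernel=config.kernel,
        round=round,
        training_hashes={
            "positives": _hash_windows(ts.positives),
            "negatives": _hash_windows(ts.negatives),
        },
    )
    return bundle


def decision_score(bundle: ModelBundle, window: WindowInstance) -> float:
    """Signed margin for one window; classify positive iff > 0."""
    return float(bundle.decision_function(bundle.featurize_windows([window]))[0])


def _score_windows(bundle: ModelBundle, windows: Sequence[WindowInstance]) -> np.ndarray:
    if not windows:
        return np.empty(0)
    return bundle.decision_function(bundle.featurize_windows(windows))


def loocv(
    ts: TrainingSet,
    config: TrainConfig = TrainConfig(),
    tables: Mapping[str, PropertyTable] | None = None,
) -> EvalMetrics:
    """Leave-one-out cross-validation over the positive set.

    Hybrid scheme (default): each positive is left out in turn and scored
    by a model trained on the remainder; negatives are scored out-of-fold
    by ``n_negative_folds`` models trained with all positives. The
    ``loo_all`` scheme leaves out every sample one at a time (quadratic;
    small sets only).
    """
    if len(ts.positives) < 3:
        raise LdmfError("loocv requires at least 3 positives")
    rng = np.random.default_rng(config.seed)
    tp = fn = tn = fp = 0

    if config.loocv_scheme == "loo_all":
        samples = [(w, +1) for w in ts.positives] + [(w, -1) for w in ts.negatives]
        for i, (held, truth) in enumerate(samples):
            pos = [w for j, (w, s) in enumerate(samples) if s > 0 and j != i]
            neg = [w for j, (w, s) in enumerate(samples) if s < 0 and j != i]
            bundle = train(TrainingSet(tuple(pos), tuple(neg)), config, tables)
            pred = decision_score(bundle, held) > 0
            if truth > 0:
                tp, fn = (tp + 1, fn) if pred else (tp, fn + 1)
            else:
                fp, tn = (fp + 1, tn) if pred else (fp, tn + 1)
        return EvalMetrics(tp=tp, fn=fn, tn=tn, fp=fp)

    if config.loocv_scheme != "hybrid":
        raise ValueError(f"unknown loocv scheme {config.loocv_scheme!r}")

    # positives: true leave-one-out
    for i, held in enumerate(ts.positives):
        rest = tuple(w for j, w in enumerate(ts.positives) if j != i)
        bundle = train(TrainingSet(rest, ts.negatives), config, tables)
        if decision_score(bundle, held) > 0:
            tp += 1
        else:
            fn += 1

    # negatives: k-fold, each fold scored by a model trained without it
    n_neg = len(ts.negatives)
    k = min(config.n_negative_folds, n_neg)
    order = rng.permutation(n_neg)
    folds = np.array_split(order, k)
    for fold in folds:
        fold_set = set(fold.tolist())
        train_neg = tuple(w for j, w in enumerate(ts.negatives) if j not in fold_set)
        held_neg = [ts.negatives[j] for j in fold]
        bundle = train(TrainingSet(ts.positives, train_neg), config, tables)
        scores = _score_windows(bundle, held_neg)
        fp += int(np.sum(scores > 0))
        tn += int(np.sum(scores <= 0))
    return EvalMetrics(tp=tp, fn=fn, tn=tn, fp=fp)


def draw_random_negatives(
    proteins: Sequence[ProteinRecord],
    n: int,
    rng: np.random.Generator,
    exclude: set[tuple[str, int]] = frozenset(),
    ss_tracks: Mapping[str, object] | None = None,
) -> list[WindowInstance]:
    """Random anchored-L windows from a proteome, excluding known sites.

    SS comes from *ss_tracks* when given, otherwise from the built-in
    propensity predictor.
    """
    model = default_propensity_model()
    candidates: list[WindowInstance] = []
    track_cache = dict(ss_tracks) if ss_tracks else {}
    for p in proteins:
        track = track_cache.get(p.id)
        if track is None:
            track = predict_ss(p, model)
            track_cache[p.id] = track
        for w in enumerate_candidates(p, "anchored_L"):
            if w.key in exclude:
                continue
            candidates.append(attach_ss(replace(w, label="negative"), track))
    if not candidates:
        raise LdmfError("proteome yielded no candidate windows")
    if n >= len(candidates):
        return candidates
    picked = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(picked)]


def active_learning_run(
    seed_positives: Sequence[WindowInstance],
    proteome: Sequence[ProteinRecord],
    decoy_pool: Sequence[WindowInstance],
    validated_hits: Sequence[WindowInstance] = (),
    config: TrainConfig = TrainConfig(),
    tables: Mapping[str, PropertyTable] | None = None,
    ss_tracks: Mapping[str, object] | None = None,
    exclude_keys: frozenset[tuple[str, int]] | set = frozenset(),
) -> list[ModelBundle]:
    """Run the multi-round protocol; returns one bundle per round.

    Round 1 trains against random proteome windows; round 2 adds hard
    negatives mined from *decoy_pool* (top ``hard_negative_quantile`` of
    round-1 scores); round 3 adds *validated_hits* to the positives. An
    empty decoy pool degenerates round 2 to the round-1 negatives (with a
    warning); empty *validated_hits* makes round-3 positives equal the
    seed set.
    """
    rng = np.random.default_rng(config.seed)
    seed_positives = tuple(seed_positives)
    # random negatives avoid the seed positives plus any additional known
    # sites the caller wants kept out of the negative pool
    exclude = {w.key for w in seed_positives} | set(exclude_keys)

    random_negs = draw_random_negatives(
        proteome, config.n_random_negatives, rng, exclude=exclude, ss_tracks=ss_tracks
    )
    provenance: dict[tuple[str, int], str] = {w.key: "known" for w in seed_positives}
    provenance.update({w.key: "random_negative" for w in random_negs})

    bundles: list[ModelBundle] = []
    ts1 = TrainingSet(seed_positives, tuple(random_negs), provenance)
    log.info("round 1: %d positives, %d random negatives", len(ts1.positives), len(ts1.negatives))
    bundles.append(train(ts1, config, tables, round=1))
    if config.n_rounds == 1:
        return bundles

    if decoy_pool:
        scores = _score_windows(bundles[0], list(decoy_pool))
        cutoff = float(np.quantile(scores, config.hard_negative_quantile))
        hard = [
            replace(w, label="negative")
            for w, s in zip(decoy_pool, scores)
            if s >= cutoff and w.label != "positive" and w.key not in exclude
        ]
    else:
        log.warning("empty decoy pool: round 2 degenerates to round-1 negatives")
        hard = []
    provenance.update({w.key: "hard_negative" for w in hard})
    negatives2 = tuple(random_negs) + tuple(hard)
    ts2 = TrainingSet(seed_positives, negatives2, provenance)
    log.info("round 2: %d positives, %d negatives (%d hard)", len(ts2.positives), len(ts2.negatives), len(hard))
    bundles.append(train(ts2, config, tables, round=2))
    if config.n_rounds == 2:
        return bundles

    validated = tuple(
        replace(w, label="positive") for w in validated_hits if w.key not in exclude
    )
    provenance.update({w.key: "experimental" for w in validated})
    validated_keys = {v.key for v in validated}
    negatives3 = tuple(w for w in negatives2 if w.key not in validated_keys)
    ts3 = TrainingSet(seed_positives + validated, negatives3, provenance)
    log.info("round 3: %d positives (%d validated), %d negatives", len(ts3.positives), len(validated), len(ts3.negatives))
    bundles.append(train(ts3, config, tables, round=3))
    return bundles


# ---------------------------------------------------------------------------
# Bundle persistence: a directory of TSV matrices + structured text


def _pwm_filename(key: tuple[str, str]) -> str:
    return f"pwm_{key[0]}_{key[1]}.tsv"


def save_model_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Write the bundle as an inspectable, diffable directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for key, pwm in bundle.pwms.items():
        df = pd.DataFrame(
            pwm.probs, index=list(pwm.alphabet), columns=range(pwm.width)
        )
        df.insert(0, "background", pwm.background)
        df.to_csv(path / _pwm_filename(key), sep="\t", float_format="%.12g")
    pd.DataFrame(
        {"mean": bundle.scaler_mean, "scale": bundle.scaler_scale}
    ).to_csv(path / "scaler.tsv", sep="\t", index_label="feature", float_format="%.12g")
    prop_rows = {
        role: {letter: t.values[letter] for letter in sorted(t.values)}
        for role, t in bundle.tables.items()
    }
    with open(path / "properties.json", "w") as fh:
        json.dump(
            {role: {"property_id": bundle.tables[role].property_id, "values": v}
             for role, v in prop_rows.items()},
            fh, indent=1, sort_keys=True,
        )
    with open(path / "svm.json", "w") as fh:
        json.dump(
            {
                "kernel": bundle.kernel,
                "gamma": bundle.gamma,
                "C": bundle.C,
                "intercept": bundle.intercept,
                "dual_coef": bundle.dual_coef.tolist(),
                "support_vectors": bundle.support_vectors.tolist(),
            },
            fh,
        )
    with open(path / "manifest.json", "w") as fh:
        json.dump(
            {
                "format": "ldmf-bundle-1",
                "layout_version": bundle.layout_version,
                "round": bundle.round,
                "n_features": N_FEATURES,
                "pseudocount": {k[0] + "_" + k[1]: p.pseudocount for k, p in bundle.pwms.items()},
                "training_hashes": dict(bundle.training_hashes),
            },
            fh, indent=1, sort_keys=True,
        )


def load_model_bundle(path: str | Path) -> ModelBundle:
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("layout_version") != LAYOUT_VERSION:
        raise LdmfError(
            f"bundle layout {manifest.get('layout_version')!r} does not match "
            f"this build ({LAYOUT_VERSION})"
        )
    pwms = {}
    for key in PWM_FEATURE_ORDER:
        df = pd.read_csv(path / _pwm_filename(key), sep="\t", index_col=0)
        background = df["background"].to_numpy()
        probs = df.drop(columns="background").to_numpy()
        alphabet = tuple(str(i) for i in df.index)
        pwms[key] = Pwm(
            alphabet=alphabet,
            probs=probs,
            background=background,
            pseudocount=float(manifest["pseudocount"][key[0] + "_" + key[1]]),
        )
    scaler = pd.read_csv(path / "scaler.tsv", sep="\t", index_col="feature")
    with open(path / "svm.json") as fh:
        svm = json.load(fh)
    with open(path / "properties.json") as fh:
        props = json.load(fh)
    tables = {
        role: PropertyTable(property_id=spec["property_id"], values=spec["values"])
        for role, spec in props.items()
    }
    return ModelBundle(
        pwms=pwms,
        tables=tables,
        scaler_mean=scaler["mean"].to_numpy(),
        scaler_scale=scaler["scale"].to_numpy(),
        support_vectors=np.asarray(svm["support_vectors"], dtype=float),
        dual_coef=np.asarray(svm["dual_coef"], dtype=float),
        intercept=float(svm["intercept"]),
        gamma=float(svm["gamma"]),
        C=float(svm["C"]),
        kernel=str(svm["kernel"]),
        layout_version=manifest["layout_version"],
        round=int(manifest["round"]),
        training_hashes=manifest["training_hashes"],
    )
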