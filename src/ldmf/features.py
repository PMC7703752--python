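"""Position weight matrices and feature-vector assembly.

The classifier sees each candidate window as a fixed 36-dimensional
vector (layout ``ldmf-v1``):

* 6 summed log-odds PWM scores — {sequence, secondary structure} x
  {core(10), upstream(20), downstream(20)}, each PWM built from the
  positive training windows only;
* 30 per-position physicochemical values — hydrophobicity, volume and
  charge for the 10 core residues.

The pad symbol ``-`` is a first-class alphabet letter (terminal motifs
must be scorable); ``X`` is treated as uninformative — it is neither
counted when building a PWM nor scored (contributes 0 log-odds) and maps
to the scale mean in physicochemical profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from ldmf.io_formats import LdmfError, PropertyTable
from ldmf.windows import WindowInstance

LAYOUT_VERSION = "ldmf-v1"
N_FEATURES = 36

AA_ALPHABET: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY") + ("-",)
SS_ALPHABET: tuple[str, ...] = ("H", "E", "C", "-")

#: floor applied to probabilities before taking logs
PROB_FLOOR = 1e-9
#: background mass reserved for the pad letter in default backgrounds
PAD_BACKGROUND = 0.01

Region = Literal["core", "upstream", "downstream"]
AlphabetKind = Literal["sequence", "ss"]

_REGION_ATTR = {
    ("sequence", "core"): "core",
    ("sequence", "upstream"): "upstream",
    ("sequence", "downstream"): "downstream",
    ("ss", "core"): "ss_core",
    ("ss", "upstream"): "ss_upstream",
    ("ss", "downstream"): "ss_downstream",
}

#: order of the six PWM features in the vector
PWM_FEATURE_ORDER: tuple[tuple[AlphabetKind, Region], ...] = (
    ("sequence", "core"),
    ("sequence", "upstream"),
    ("sequence", "downstream"),
    ("ss", "core"),
    ("ss", "upstream"),
    ("ss", "downstream"),
)


@dataclass(frozen=True)
class Pwm:
    """Column-stochastic position probability matrix with log-odds scoring."""

    alphabet: tuple[str, ...]
    probs: np.ndarray  # shape (len(alphabet), width)
    background: np.ndarray  # shape (len(alphabet),), sums to 1
    pseudocount: float

    def __post_init__(self) -> None:
        if self.probs.shape[0] != len(self.alphabet):
            raise ValueError("probs rows must match alphabet size")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def index(self) -> Mapping[str, int]:
        return {letter: i for i, letter in enumerate(self.alphabet)}


def make_background(
    frequencies: Mapping[str, float],
    alphabet: Sequence[str] = AA_ALPHABET,
    pad_mass: float = PAD_BACKGROUND,
) -> np.ndarray:
    """Background vector over *alphabet*, reserving *pad_mass* for ``-``.

    Letters missing from *frequencies* get zero mass (floored at scoring
    time); the named letters are rescaled to ``1 - pad_mass``.
    """
    named = {k: v for k, v in frequencies.items() if k in alphabet and k != "-"}
    total = sum(named.values())
    bg = np.zeros(len(alphabet))
    for i, letter in enumerate(alphabet):
        if letter == "-":
            bg[i] = pad_mass
        elif letter in named:
            bg[i] = named[letter] / total * (1.0 - pad_mass)
    return bg / bg.sum()


def uniform_ss_background(pad_mass: float = PAD_BACKGROUND) -> np.ndarray:
    return make_background(
        {"H": 1 / 3, "E": 1 / 3, "C": 1 / 3}, alphabet=SS_ALPHABET, pad_mass=pad_mass
    )


def build_pwm(
    windows: Sequence[WindowInstance],
    region: Region = "core",
    alphabet_kind: AlphabetKind = "sequence",
    pseudocount: float = 1.0,
    background: np.ndarray | Mapping[str, float] | None = None,
) -> Pwm:
    """Laplace-smoothed PWM from the given region of labelled windows.

    ``probs[letter, j] = (count + pseudocount) / (n_j + pseudocount * |alphabet|)``
    where ``n_j`` is the number of counted letters in column j (X is not
    counted). With ``pseudocount == 0`` absent letters get probability 0;
    :func:`score_pwm` floors them before the log.
    """
    if not windows:
        raise LdmfError("cannot build a PWM from zero windows")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    alphabet = AA_ALPHABET if alphabet_kind == "sequence" else SS_ALPHABET
    attr = _REGION_ATTR[(alphabet_kind, region)]
    segments = []
    for w in windows:
        seg = getattr(w, attr)
        if seg is None:
            raise LdmfError("attach_ss first: window has no SS annotation")
        segments.append(seg)
    widths = {len(s) for s in segments}
    if len(widths) != 1:
        raise LdmfError(f"windows disagree on {region} width: {sorted(widths)}")
    width = widths.pop()

    idx = {letter: i for i, letter in enumerate(alphabet)}
    counts = np.zeros((len(alphabet), width))
    for seg in segments:
        for j, letter in enumerate(seg):
            if letter == "X":
                continue  # unknown residue: uninformative
            counts[idx[letter], j] += 1

    denom = counts.sum(axis=0) + pseudocount * len(alphabet)
    # all-X column with zero pseudocount: fall back to uniform
    safe = np.where(denom > 0, denom, 1.0)
    probs = (counts + pseudocount) / safe
    probs[:, denom == 0] = 1.0 / len(alphabet)

    if background is None:
        if alphabet_kind == "sequence":
            from ldmf.resources import load_background_composition

            bg = make_background(load_background_composition(), alphabet)
        else:
            bg = uniform_ss_background()
    elif isinstance(background, np.ndarray):
        bg = background.astype(float)
    else:
        # caller-specified frequencies; missing letters (typically '-') get 0
        bg = np.array([float(background.get(a, 0.0)) for a in alphabet])
        bg = bg / bg.sum()
    return Pwm(
        alphabet=alphabet, probs=probs, background=bg, pseudocount=float(pseudocount)
    )


def score_pwm(pwm: Pwm, segment: str) -> float:
    """Natural-log log-odds of *segment* under *pwm* vs its background.

    Probabilities (and background entries) are floored at ``1e-9`` before
    the log; ``X`` positions contribute 0.
    """
    if len(segment) != pwm.width:
        raise LdmfError(
            f"segment length {len(segment)} does not match PWM width {pwm.width}"
        )
    idx = pwm.index
    total = 0.0
    for j, letter in enumerate(segment):
        if letter == "X":
            continue
        try:
            i = idx[letter]
        except KeyError:
            raise LdmfError(f"letter {letter!r} not in PWM alphabet") from None
        p = max(float(pwm.probs[i, j]), PROB_FLOOR)
        b = max(float(pwm.background[i]), PROB_FLOOR)
        total += math.log(p / b)
    return total


def physicochemical_profile(
    core: str, tables: Mapping[str, PropertyTable]
) -> np.ndarray:
    """Concatenated hydrophobicity/volume/charge values of the 10 core residues."""
    if len(core) != 10:
        raise LdmfError("core must be 10 residues")
    from ldmf.resources import PROPERTY_ROLES

    missing = [r for r in PROPERTY_ROLES if r not in tables]
    if missing:
        raise LdmfError(f"missing property table(s): {missing}")
    return np.array(
        [tables[role].value(c) for role in PROPERTY_ROLES for c in core], dtype=float
    )


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    layout_version: str = LAYOUT_VERSION

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def featurize(
    window: WindowInstance,
    pwms: Mapping[tuple[AlphabetKind, Region], Pwm],
    tables: Mapping[str, PropertyTable],
) -> FeatureVector:
    """Assemble the 36-dimensional ``ldmf-v1`` vector for one window."""
    if not window.has_ss:
        raise LdmfError("attach_ss first: window has no SS annotation")
    values = np.empty(N_FEATURES)
    for k, key in enumerate(PWM_FEATURE_ORDER):
        kind, region = key
        segment = getattr(window, _REGION_ATTR[(kind, region)])
        values[k] = score_pwm(pwms[key], segment)
    values[6:] = physicochemical_profile(window.core, tables)
    return FeatureVector(values=values)


def _logodds_table(pwm: Pwm) -> np.ndarray:
    """Per-(letter, position) log-odds with an extra all-zero row for X."""
    p = np.maximum(pwm.probs, PROB_FLOOR)
    b = np.maximum(pwm.background, PROB_FLOOR)[:, None]
    table = np.log(p / b)
    return np.vstack([table, np.zeros((1, pwm.width))])


def _encode_segments(segments: list[str], alphabet: Sequence[str]) -> np.ndarray:
    """Integer-encode letters; X (or anything unknown) maps to the zero row."""
    x_row = len(alphabet)
    lut = np.full(128, -1, dtype=np.int64)
    for i, letter in enumerate(alphabet):
        lut[ord(letter)] = i
    lut[ord("X")] = x_row
    codes = np.frombuffer("".join(segments).encode("ascii"), dtype=np.uint8)
    enc = lut[codes].reshape(len(segments), -1)
    if (enc < 0).any():
        bad = {s for s, row in zip(segments, enc) if (row < 0).any()}
        raise LdmfError(f"letters outside PWM alphabet in {sorted(bad)[:3]!r}")
    return enc


def featurize_many(
    windows: Iterable[WindowInstance],
    pwms: Mapping[tuple[AlphabetKind, Region], Pwm],
    tables: Mapping[str, PropertyTable],
) -> np.ndarray:
    """Vectorized :func:`featurize` over many windows; rows match one-by-one."""
    windows = list(windows)
    if not windows:
        return np.empty((0, N_FEATURES))
    X = np.empty((len(windows), N_FEATURES))
    for k, key in enumerate(PWM_FEATURE_ORDER):
        kind, region = key
        attr = _REGION_ATTR[(kind, region)]
        segments = []
        for w in windows:
            seg = getattr(w, attr)
            if seg is None:
                raise LdmfError("attach_ss first: window has no SS annotation")
            segments.append(seg)
        pwm = pwms[key]
        widths = {len(s) for s in segments}
        if widths != {pwm.width}:
            raise LdmfError(
                f"segment widths {sorted(widths)} do not match PWM width {pwm.width}"
            )
        enc = _encode_segments(segments, pwm.alphabet)
        table = _logodds_table(pwm)
        X[:, k] = table[enc, np.arange(pwm.width)].sum(axis=1)

    from ldmf.resources import PROPERTY_ROLES

    missing = [r for r in PROPERTY_ROLES if r not in tables]
    if missing:
        raise LdmfError(f"missing property table(s): {missing}")
    cores = _encode_segments([w.core for w in windows], AA_ALPHABET)
    for t, role in enumerate(PROPERTY_ROLES):
        scale = tables[role]
        vals = np.array([scale.values[a] for a in AA_ALPHABET[:-1]] + [scale.mean] * 2)
        X[:, 6 + 10 * t : 6 + 10 * (t + 1)] = vals[cores]
    return X
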