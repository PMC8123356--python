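"""Pairwise preference learning from offline-optimal assignment decisions.

The central object is an anti-symmetric neural comparator ``C(x, y)`` over
pairs of assignment feature vectors.  The network consists of two
weight-shared, cross-wired towers: at every layer the weight matrix mapping
the first input to the first tower equals the matrix mapping the second
input to the second tower (and vice versa for the cross connections), and
the bias is shared.  The output head scores the *difference* of the two top
hidden vectors through a sigmoid.  Two properties therefore hold by
construction, for any weights:

* reflexivity   — C(x, x) = 0.5;
* anti-symmetry — C(x, y) + C(y, x) = 1.

Training data are (chosen, rejected) pairs distilled from decisions made by
an offline-optimal solver; training minimises binary cross-entropy with
target C(chosen, rejected) = 1 (a RankNet-style probabilistic reading of
the comparator).  The trained comparator is used online either through an
all-pairs majority-vote tournament (single best choice) or as a
partial-order operator for ordered-pool insertion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FeatureVector",
    "PreferencePair",
    "DecisionEvent",
    "ComparatorModel",
    "ComparatorHyperparams",
    "TrainingDivergedError",
    "SchemaMismatchError",
    "compare",
    "compare_batch",
    "build_training_pairs",
    "train_comparator",
    "majority_vote_select",
    "insert_by_partial_order",
    "save_pairs",
    "load_pairs",
    "save_model",
    "load_model",
]


class SchemaMismatchError(ValueError):
    """Inputs do not share the comparator's feature schema."""


class TrainingDivergedError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length numeric description of one assignment option."""

    values: np.ndarray
    schema_id: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("feature vector must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PreferencePair:
    preferred: FeatureVector
    rejected: FeatureVector
    source_event: str = ""

    def __post_init__(self):
        if self.preferred.schema_id != self.rejected.schema_id:
            raise SchemaMismatchError(
                f"pair mixes schemas {self.preferred.schema_id!r} and "
                f"{self.rejected.schema_id!r}"
            )


@dataclass(frozen=True)
class DecisionEvent:
    """One decision instant: the option taken and the options passed over."""

    time: float
    chosen: FeatureVector
    alternatives: tuple[FeatureVector, ...]
    event_id: str = ""


@dataclass
class ComparatorHyperparams:
    hidden: tuple[int, ...] = (32, 32)
    activation: str = "tanh"
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 64
    weight_decay: float = 0.0


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "tanh": (np.tanh, lambda u: 1.0 - np.tanh(u) ** 2),
    "relu": (lambda u: np.maximum(u, 0.0), lambda u: (u > 0).astype(float)),
    "identity": (lambda u: u, lambda u: np.ones_like(u)),
}


def _sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ComparatorModel:
    """Cross-wired shared-weight comparator.

    Layer ``l`` holds ``(A_l, B_l, b_l)``: ``A`` maps the same-side stream,
    ``B`` the opposite-side stream.  The head weight ``w`` scores the
    difference of the two top hidden vectors; it has no bias, which keeps
    C(x, x) pinned at 0.5.

    ``mu``/``sigma`` are a per-feature affine standardization fitted on the
    training vectors and applied identically to both inputs (identical
    transforms preserve both structural properties).
    """

    schema_id: str
    input_dim: int
    layers: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    head: np.ndarray
    activation: str = "tanh"
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    hyperparams: ComparatorHyperparams = field(default_factory=ComparatorHyperparams)
    seed: int | None = None
    loss_history: list[float] = field(default_factory=list)

    # -- forward ---------------------------------------------------------
    def _normalize(self, X: np.ndarray) -> np.ndarray:
        if self.mu is None:
            return X
        return (X - self.mu) / self.sigma

    def _towers(self, X: np.ndarray, Y: np.ndarray):
        """Hidden activations of both towers; returns per-layer caches."""
        act, _ = _ACTIVATIONS[self.activation]
        h1, h2 = self._normalize(X), self._normalize(Y)
        cache = []
        for A, B, b in self.layers:
            u1 = h1 @ A.T + h2 @ B.T + b
            u2 = h2 @ A.T + h1 @ B.T + b
            cache.append((h1, h2, u1, u2))
            h1, h2 = act(u1), act(u2)
        return h1, h2, cache

    def scores(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        h1, h2, _ = self._towers(np.atleast_2d(X), np.atleast_2d(Y))
        return _sigmoid((h1 - h2) @ self.head)


def random_comparator(
    schema_id: str,
    input_dim: int,
    hyperparams: ComparatorHyperparams | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ComparatorModel:
    """A freshly initialised comparator (Glorot-scaled weights)."""
    hp = hyperparams or ComparatorHyperparams()
    if rng is None:
        rng = np.random.default_rng(seed)
    layers = []
    d_in = input_dim
    for d_out in hp.hidden:
        # each unit sees both streams: effective fan-in is 2 * d_in
        scale = np.sqrt(2.0 / (2 * d_in + d_out))
        A = rng.normal(0.0, scale, size=(d_out, d_in))
        B = rng.normal(0.0, scale, size=(d_out, d_in))
        b = np.zeros(d_out)
        layers.append((A, B, b))
        d_in = d_out
    head = rng.normal(0.0, np.sqrt(1.0 / d_in), size=d_in)
    return ComparatorModel(
        schema_id=schema_id,
        input_dim=input_dim,
        layers=layers,
        head=head,
        activation=hp.activation,
        hyperparams=hp,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _check_schema(model: ComparatorModel, *vecs: FeatureVector) -> None:
    for v in vecs:
        if v.schema_id != model.schema_id:
            raise SchemaMismatchError(
                f"vector schema {v.schema_id!r} != model schema {model.schema_id!r}"
            )
        if len(v) != model.input_dim:
            raise SchemaMismatchError(
                f"vector length {len(v)} != model input dim {model.input_dim}"
            )


def compare(model: ComparatorModel, x: FeatureVector, y: FeatureVector) -> float:
    """Preference score C(x, y) in [0, 1]; > 0.5 means x is preferred."""
    _check_schema(model, x, y)
    return float(model.scores(x.values[None, :], y.values[None, :])[0])


def compare_batch(model: ComparatorModel, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorised C over row-aligned stacks of raw feature values."""
    return model.scores(np.asarray(X, float), np.asarray(Y, float))


def build_training_pairs(
    events: Sequence[DecisionEvent], warn: Callable[[str], None] | None = None
) -> list[PreferencePair]:
    """One (chosen, rejected) pair per passed-over alternative of each event."""
    if len(events) == 0:
        raise ValueError("no decision events supplied")
    pairs: list[PreferencePair] = []
    for ev in events:
        if len(ev.alternatives) == 0:
            if warn is not None:
                warn(f"event {ev.event_id or ev.time}: no alternatives, skipped")
            continue
        for alt in ev.alternatives:
            pairs.append(PreferencePair(ev.chosen, alt, source_event=ev.event_id))
    return pairs


def train_comparator(
    pairs: Sequence[PreferencePair],
    hyperparams: ComparatorHyperparams | None = None,
    seed: int = 0,
) -> ComparatorModel:
    """Fit the comparator on (preferred, rejected) pairs by Adam/BCE.

    The target is C(preferred, rejected) = 1.  All randomness (init and
    shuffling) derives from ``seed``; two runs with the same seed produce
    identical weights.
    """
    if len(pairs) == 0:
        raise ValueError("cannot train on an empty pair list")
    hp = hyperparams or ComparatorHyperparams()
    schema = pairs[0].preferred.schema_id
    P = np.stack([p.preferred.values for p in pairs])
    R = np.stack([p.rejected.values for p in pairs])
    n, d = P.shape

    rng = np.random.default_rng(seed)
    model = random_comparator(schema, d, hp, rng=rng, seed=seed)

    allv = np.vstack([P, R])
    model.mu = allv.mean(axis=0)
    sig = allv.std(axis=0)
    sig[sig < 1e-9] = 1.0
    model.sigma = sig

    act, dact = _ACTIVATIONS[hp.activation]

    # Adam state, one slot per parameter array
    params: list[np.ndarray] = []
    for A, B, b in model.layers:
        params.extend([A, B, b])
    params.append(model.head)
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, hp.batch_size):
            idx = order[lo : lo + hp.batch_size]
            Xb, Yb = P[idx], R[idx]
            h1, h2, cache = model._towers(Xb, Yb)
            z = (h1 - h2) @ model.head
            s = _sigmoid(z)
            # BCE with target 1: -log s
            loss = float(np.mean(-np.log(np.clip(s, 1e-12, None))))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}"
                )
            epoch_loss += loss * len(idx)

            dz = (s - 1.0) / len(idx)                    # dL/dz
            grads = [np.zeros_like(p) for p in params]
            grads[-1] = (h1 - h2).T @ dz                 # head
            g1 = dz[:, None] * model.head[None, :]
            g2 = -g1
            for li in range(len(model.layers) - 1, -1, -1):
                A, B, b = model.layers[li]
                h1p, h2p, u1, u2 = cache[li]
                du1 = g1 * dact(u1)
                du2 = g2 * dact(u2)
                grads[3 * li + 0] = du1.T @ h1p + du2.T @ h2p   # dA
                grads[3 * li + 1] = du1.T @ h2p + du2.T @ h1p   # dB
                grads[3 * li + 2] = du1.sum(axis=0) + du2.sum(axis=0)
                g1 = du1 @ A + du2 @ B
                g2 = du2 @ A + du1 @ B

            step += 1
            lr_t = hp.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for p, g, m, v in zip(params, grads, m_state, v_state):
                if hp.weight_decay:
                    g = g + hp.weight_decay * p
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                p -= lr_t * m / (np.sqrt(v) + eps)
        model.loss_history.append(epoch_loss / n)

    return model


def majority_vote_select(
    model: ComparatorModel,
    candidates: Sequence[FeatureVector],
    rng: np.random.Generator,
) -> int:
    """All-pairs tournament; returns the index of a maximum-point candidate.

    Each unordered pair is compared once; a strict winner (C deviating from
    0.5) earns one point, an exact tie earns each half a point.  Ties for
    the top score are broken uniformly at random with ``rng``.
    """
    ncand = len(candidates)
    if ncand == 0:
        raise ValueError("no candidates to select from")
    if ncand == 1:
        return 0
    _check_schema(model, *candidates)
    ii, jj = np.triu_indices(ncand, k=1)
    V = np.stack([c.values for c in candidates])
    s = compare_batch(model, V[ii], V[jj])
    points = np.zeros(ncand)
    tie = np.isclose(s, 0.5, rtol=0.0, atol=1e-12)
    points += np.bincount(ii[tie], minlength=ncand) * 0.5
    points += np.bincount(jj[tie], minlength=ncand) * 0.5
    win_i = (~tie) & (s > 0.5)
    win_j = (~tie) & (s < 0.5)
    points += np.bincount(ii[win_i], minlength=ncand).astype(float)
    points += np.bincount(jj[win_j], minlength=ncand).astype(float)
    best = np.flatnonzero(points == points.max())
    return int(best[rng.integers(len(best))]) if len(best) > 1 else int(best[0])


def insert_by_partial_order(
    model: ComparatorModel,
    ordered_pool: Sequence[FeatureVector],
    new_item: FeatureVector,
) -> list[FeatureVector]:
    """Insert ``new_item`` at the first rank where it beats the incumbent.

    Scanning from the highest rank, the item is placed before the first
    incumbent it is (weakly) preferred over (C >= 0.5); otherwise it is
    appended last.  The relative order of incumbents is unchanged.
    """
    _check_schema(model, new_item, *ordered_pool)
    pool = list(ordered_pool)
    if pool:
        s = compare_batch(
            model,
            np.tile(new_item.values, (len(pool), 1)),
            np.stack([p.values for p in pool]),
        )
        beats = np.flatnonzero(s >= 0.5)
        pos = int(beats[0]) if len(beats) else len(pool)
    else:
        pos = 0
    pool.insert(pos, new_item)
    return pool


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_pairs(pairs: Sequence[PreferencePair], path) -> None:
    """Write training pairs as JSON lines (one pair per line)."""
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                json.dumps(
                    {
                        "schema_id": p.preferred.schema_id,
                        "preferred": p.preferred.values.tolist(),
                        "rejected": p.rejected.values.tolist(),
                        "source_event": p.source_event,
                    }
                )
                + "\n"
            )


def load_pairs(path) -> list[PreferencePair]:
    out = []
    with open(path) as fh:
        for line in fh:
            doc = json.loads(line)
            out.append(
                PreferencePair(
                    FeatureVector(doc["preferred"], doc["schema_id"]),
                    FeatureVector(doc["rejected"], doc["schema_id"]),
                    source_event=doc.get("source_event", ""),
                )
            )
    return out


def save_model(model: ComparatorModel, path) -> None:
    """Write the comparator as a portable JSON archive."""
    doc = {
        "schema_id": model.schema_id,
        "input_dim": model.input_dim,
        "activation": model.activation,
        "seed": model.seed,
        "hyperparams": {
            "hidden": list(model.hyperparams.hidden),
            "activation": model.hyperparams.activation,
            "learning_rate": model.hyperparams.learning_rate,
            "epochs": model.hyperparams.epochs,
            "batch_size": model.hyperparams.batch_size,
            "weight_decay": model.hyperparams.weight_decay,
        },
        "mu": None if model.mu is None else model.mu.tolist(),
        "sigma": None if model.sigma is None else model.sigma.tolist(),
        "layers": [
            {"A": A.tolist(), "B": B.tolist(), "b": b.tolist()}
            for A, B, b in model.layers
        ],
        "head": model.head.tolist(),
        "loss_history": model.loss_history,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ComparatorModel:
    with open(path) as fh:
        doc = json.load(fh)
    hp = ComparatorHyperparams(
        hidden=tuple(doc["hyperparams"]["hidden"]),
        activation=doc["hyperparams"]["activation"],
        learning_rate=doc["hyperparams"]["learning_rate"],
        epochs=doc["hyperparams"]["epochs"],
        batch_size=doc["hyperparams"]["batch_size"],
        weight_decay=doc["hyperparams"].get("weight_decay", 0.0),
    )
    return ComparatorModel(
        schema_id=doc["schema_id"],
        input_dim=doc["input_dim"],
        layers=[
            (np.array(l["A"]), np.array(l["B"]), np.array(l["b"]))
            for l in doc["layers"]
        ],
        head=np.array(doc["head"]),
        activation=doc["activation"],
        mu=None if doc["mu"] is None else np.array(doc["mu"]),
        sigma=None if doc["sigma"] is None else np.array(doc["sigma"]),
        hyperparams=hp,
        seed=doc["seed"],
        loss_history=list(doc.get("loss_history", [])),
    )
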