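"""End-to-end training of the graph-LSTM tile-risk model, plus metrics.

The model is exposed as a scikit-learn style estimator,
:class:`GraphLSTMTileClassifier`: ``fit`` consumes a list of
:class:`TileSequence` (one per map tile: weekly node features, normalized
adjacency, and case hyperedge groups) with binary tile labels, and trains
the attention-aggregation + GCN + fusion + LSTM stack by per-tile
adaptive-moment gradient descent on binary cross-entropy.  ``predict_proba``
returns tile risk scores; ``predict_poi_scores`` returns per-venue scores
from the same readout head applied before mean pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .autograd import Adam, Tensor, as_array, sigmoid
from .dataio import CaseProfile, CheckinRecord, POIRecord, TileID
from .gcn import GcnParams, gcn_forward, normalized_adjacency
from .graph import AttentionParams, aggregate_features, build_tile_graph
from .splice import SpliceParams, build_feature_vectors, splice_checkins
from .temporal import FusionParams, LstmParams, LstmState, fuse, lstm_cell


# ---------------------------------------------------------------------------
# tile sequences (model input)
# ---------------------------------------------------------------------------

@dataclass
class TileSequence:
    """Precomputed weekly model inputs for one tile.

    ``weeks`` holds one ``(X_t, A_norm_t, edge_groups_t)`` triple per week;
    edge groups are ``(member_index_array, case_multiplicity)`` pairs with
    duplicate case edges over the same member set collapsed.
    """

    tile: TileID
    node_ids: list[str]
    weeks: list[tuple[np.ndarray, np.ndarray, list]]
    n_checkins: int = 0
    n_cases: int = 0


def build_tile_sequences(
    pois: list[POIRecord],
    checkins: list[CheckinRecord],
    cases: list[CaseProfile],
    n_weeks: int,
    params: SpliceParams | None = None,
    category_prior: np.ndarray | None = None,
) -> list[TileSequence]:
    """Splice check-ins, build per-tile weekly graphs, and cache model inputs.

    ``category_prior`` optionally rescales the category one-hot block of the
    node features by ``1 + prior`` — a way to inject prior knowledge of how
    strongly each food-access category drives risk.
    """
    params = params or SpliceParams()
    splice_checkins(checkins, pois, params)
    by_tile: dict[TileID, list[POIRecord]] = {}
    for p in pois:
        by_tile.setdefault(p.tile, []).append(p)
    checkins_by_tile: dict[TileID, list[CheckinRecord]] = {t: [] for t in by_tile}
    poi_tile = {p.poi_id: p.tile for p in pois}
    for c in checkins:
        if c.matched_poi is not None:
            checkins_by_tile[poi_tile[c.matched_poi]].append(c)
    cases_by_tile: dict[TileID, list[CaseProfile]] = {t: [] for t in by_tile}
    for case in cases:
        if case.tile in cases_by_tile:
            cases_by_tile[case.tile].append(case)
    out: list[TileSequence] = []
    for tile in sorted(by_tile):
        feats = build_feature_vectors(
            by_tile[tile], checkins_by_tile[tile], params,
            tile=tile, n_weeks=n_weeks, use_matches=True,
        )
        weeks = []
        for t in range(1, n_weeks + 1):
            g = build_tile_graph(feats, cases_by_tile[tile], t, tile=tile)
            X = g.X
            if category_prior is not None:
                X = X.copy()
                X[:, 2:12] *= 1.0 + np.asarray(category_prior, dtype=float)
            groups: dict[tuple[int, ...], int] = {}
            for e in g.edges:
                groups[e.member_pois] = groups.get(e.member_pois, 0) + 1
            edge_groups = [(np.array(m), mult) for m, mult in sorted(groups.items())]
            weeks.append((X, normalized_adjacency(g.A), edge_groups))
        out.append(
            TileSequence(
                tile=tile,
                node_ids=[f.poi_id for f in feats],
                weeks=weeks,
                n_checkins=len(checkins_by_tile[tile]),
                n_cases=len(cases_by_tile[tile]),
            )
        )
    return out


def split_tiles(tiles, train_fraction: float = 0.7, seed: int = 0):
    """Disjoint, exhaustive, seed-deterministic train/test split of tiles."""
    tiles = list(tiles)
    if len(tiles) < 2:
        raise ValueError("need at least 2 tiles to split")
    n_train = round(len(tiles) * train_fraction)
    if n_train == 0 or n_train == len(tiles):
        raise ValueError("train_fraction leaves one side of the split empty")
    order = np.random.default_rng(seed).permutation(len(tiles))
    train = [tiles[i] for i in sorted(order[:n_train])]
    test = [tiles[i] for i in sorted(order[n_train:])]
    return train, test


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse(actual, predicted) -> float:
    """Root-mean-square error sqrt(mean((a_i - f_i)^2))."""
    a = np.asarray(actual, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if a.shape != f.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length and nonempty")
    return float(np.sqrt(np.mean((a - f) ** 2)))


def recall(tp_tweets: int, fn_cases: int) -> float:
    """Visit-level recall percentage, 100 * TP / (TP + FN).

    True positives are counted in check-ins (visits credited to correctly
    flagged risky tiles); false negatives in cases missed by the prediction.
    """
    if tp_tweets < 0 or fn_cases < 0:
        raise ValueError("counts must be nonnegative")
    total = tp_tweets + fn_cases
    if total == 0:
        raise ValueError("tp + fn must be positive")
    return 100.0 * tp_tweets / total


@dataclass
class EvalReport:
    """Held-out metrics plus per-tile predictions."""

    rmse: float
    accuracy: float
    recall: float
    per_tile: dict[TileID, tuple[float, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "accuracy": self.accuracy,
            "recall": self.recall,
            "per_tile": {str(t): [s, l] for t, (s, l) in sorted(self.per_tile.items())},
        }


def evaluate(
    model: "GraphLSTMTileClassifier",
    sequences: list[TileSequence],
    true_scores: dict[TileID, float],
    true_labels: dict[TileID, int],
) -> EvalReport:
    """Score held-out tiles.

    Accuracy is the percentage of tiles whose predicted label (risk score
    thresholded at 0.5) matches the planted label.  Recall counts, over truly
    risky tiles only, spliced check-ins in correctly flagged tiles as true
    positives and case profiles in missed tiles as false negatives.  RMSE
    compares predicted risk scores with the planted tile scores.
    """
    if not sequences:
        raise ValueError("empty test set")
    probs = model.predict_proba(sequences)[:, 1]
    per_tile: dict[TileID, tuple[float, int]] = {}
    correct = 0
    tp_tweets = 0
    fn_cases = 0
    a, f = [], []
    for seq, p in zip(sequences, probs):
        pred_label = int(p > 0.5)
        truth = true_labels[seq.tile]
        per_tile[seq.tile] = (float(p), pred_label)
        correct += int(pred_label == truth)
        if truth == 1:
            if pred_label == 1:
                tp_tweets += seq.n_checkins
            else:
                fn_cases += seq.n_cases
        a.append(true_scores[seq.tile])
        f.append(p)
    acc = 100.0 * correct / len(sequences)
    rec = recall(tp_tweets, fn_cases) if (tp_tweets + fn_cases) > 0 else 100.0
    return EvalReport(rmse=rmse(a, f), accuracy=acc, recall=rec, per_tile=per_tile)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

_EPS = 1e-12


class GraphLSTMTileClassifier(BaseEstimator, ClassifierMixin):
    """Graph-convolutional LSTM classifier of per-tile risk.

    Weekly pipeline per tile: case hyperedges are attention-aggregated onto
    venue features, a stacked first-order spectral GCN convolves them over
    the clique-expanded adjacency, the result is fused with the raw features
    (delta * X + (1 - alpha) * H) and fed to a venue-shared LSTM; hidden
    states at the final week are mean-pooled through an affine + sigmoid
    readout to a tile risk score.  Trained with binary cross-entropy and
    per-tile adaptive-moment updates; a validation slice of the training
    tiles drives early stopping.

    Parameters
    ----------
    hidden_gcn : width of the GCN hidden layer(s).
    gcn_layers : number of stacked convolution layers (output width returns
        to the input width so fusion shapes agree).
    lstm_hidden : LSTM hidden size.
    heads : attention heads in hyperedge aggregation.
    delta, alpha : fusion weights of raw vs convolved features.
    learning_rate : Adam step size (0 leaves weights at initialization).
    batch_size : tiles per gradient step; averaging gradients over several
        tiles keeps isolated mislabeled tiles from being memorized.
    lr_decay : per-epoch multiplicative learning-rate decay.
    grad_clip : global gradient-norm ceiling per step (0 disables); tames
        the overshoot spikes recurrent nets produce when leaving the
        initial loss plateau.
    epochs, patience, val_fraction, min_epochs : training schedule and early
        stopping (patience starts counting after ``min_epochs``).
    random_state : seed for initialization, shuffling, and the val split.

    Attributes (after fit)
    ----------------------
    classes_ : array([0, 1]).
    loss_trace_ : mean training BCE per epoch.
    n_iter_ : epochs actually run.
    """

    def __init__(self, hidden_gcn: int = 32, gcn_layers: int = 2,
                 lstm_hidden: int = 16, heads: int = 1,
                 delta: float = 0.5, alpha: float = 0.5,
                 leaky_slope: float = 0.2, learning_rate: float = 0.02,
                 batch_size: int = 8, lr_decay: float = 0.97,
                 grad_clip: float = 5.0,
                 epochs: int = 150, patience: int = 20, min_epochs: int = 30,
                 val_fraction: float = 0.1, random_state: int = 0,
                 verbose: bool = False):
        self.hidden_gcn = hidden_gcn
        self.gcn_layers = gcn_layers
        self.lstm_hidden = lstm_hidden
        self.heads = heads
        self.delta = delta
        self.alpha = alpha
        self.leaky_slope = leaky_slope
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.lr_decay = lr_decay
        self.grad_clip = grad_clip
        self.epochs = epochs
        self.patience = patience
        self.min_epochs = min_epochs
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.verbose = verbose

    # -- parameter plumbing ------------------------------------------------
    def _init_params(self, dim: int, rng: np.random.Generator) -> dict:
        def u(shape, fan_in):
            lim = 1.0 / np.sqrt(fan_in)
            return Tensor(rng.uniform(-lim, lim, shape), requires_grad=True)

        p = {
            "att_Wc": u((dim, dim), dim),
            "head_w": u(self.lstm_hidden, self.lstm_hidden),
            "head_b": Tensor(np.zeros(1), requires_grad=True),
        }
        for k in range(self.heads):
            p[f"att_W{k}"] = u((dim, dim), dim)
            p[f"att_b{k}"] = u(2 * dim, 2 * dim)
        dims = [dim] + [self.hidden_gcn] * max(self.gcn_layers - 1, 0) + [dim]
        for i, (d_in, d_out) in enumerate(zip(dims[:-1], dims[1:])):
            p[f"gcn_W{i}"] = u((d_in, d_out), d_in)
            p[f"gcn_b{i}"] = Tensor(np.zeros(d_out), requires_grad=True)
        fan = dim + self.lstm_hidden
        for gate in ("F", "I", "O", "g"):
            p[f"lstm_W{gate}"] = u((fan, self.lstm_hidden), fan)
        for gate in ("F", "I", "O", "C"):
            p[f"lstm_b{gate}"] = Tensor(np.zeros(self.lstm_hidden), requires_grad=True)
        return p

    def _views(self, p: dict):
        att = AttentionParams(
            K=self.heads,
            W_c=p["att_Wc"],
            W=[p[f"att_W{k}"] for k in range(self.heads)],
            b=[p[f"att_b{k}"] for k in range(self.heads)],
            leaky_slope=self.leaky_slope,
        )
        n_layers = max(self.gcn_layers, 1)
        gcn = GcnParams(
            weights=[p[f"gcn_W{i}"] for i in range(n_layers)],
            biases=[p[f"gcn_b{i}"] for i in range(n_layers)],
        )
        lstm = LstmParams(
            W_F=p["lstm_WF"], W_I=p["lstm_WI"], W_O=p["lstm_WO"], W_g=p["lstm_Wg"],
            b_F=p["lstm_bF"], b_I=p["lstm_bI"], b_O=p["lstm_bO"], b_C=p["lstm_bC"],
        )
        fusion = FusionParams(delta=self.delta, alpha=self.alpha)
        return att, gcn, lstm, fusion

    def _forward_tile(self, seq: TileSequence, p: dict, per_node: bool = False):
        att, gcn, lstm, fusion = self._views(p)
        n = len(seq.node_ids)
        state = LstmState.zeros(n, self.lstm_hidden)
        for X_t, A_norm, groups in seq.weeks:
            Xa = aggregate_features(X_t, groups, att) if groups else X_t
            H = gcn_forward(Xa, None, gcn, A_norm=A_norm)
            Xp = fuse(X_t, H, fusion)
            state = lstm_cell(Xp, state, lstm)
        node_logits = state.h @ p["head_w"] + p["head_b"]
        if per_node:
            return sigmoid(node_logits)
        pooled = state.h.mean(axis=0)
        logit = pooled @ p["head_w"] + p["head_b"]
        return sigmoid(logit)

    @staticmethod
    def _bce(prob, y: int):
        if y == 1:
            return -((prob + _EPS).log().sum())
        return -((1.0 - prob + _EPS).log().sum())

    # -- sklearn API -------------------------------------------------------
    def fit(self, X: list[TileSequence], y):
        y = np.asarray(y, dtype=int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ValueError("need at least one training tile")
        if any(len(seq.weeks) < 2 for seq in X):
            raise ValueError("need at least two weeks per tile")
        self.classes_ = np.array([0, 1])
        dim = X[0].weeks[0][0].shape[1]
        self.n_features_in_ = dim
        rng = np.random.default_rng(self.random_state)
        params = self._init_params(dim, rng)
        names = sorted(params)
        opt = Adam([params[k] for k in names], lr=self.learning_rate)

        # validation slice for early stopping
        idx = rng.permutation(len(X))
        n_val = int(round(self.val_fraction * len(X)))
        n_val = min(n_val, len(X) - 1)
        val_idx, tr_idx = idx[:n_val], idx[n_val:]

        best_val = np.inf
        best_snapshot = {k: params[k].data.copy() for k in names}
        stall = 0
        self.loss_trace_ = []
        for epoch in range(self.epochs):
            opt.lr = self.learning_rate * self.lr_decay**epoch
            order = rng.permutation(tr_idx)
            losses = []
            for start in range(0, len(order), self.batch_size):
                batch = order[start : start + self.batch_size]
                opt.zero_grad()
                total = None
                for i in batch:
                    prob = self._forward_tile(X[i], params)
                    loss = self._bce(prob, y[i])
                    losses.append(float(as_array(loss)))
                    if not np.isfinite(losses[-1]):
                        raise FloatingPointError(
                            f"non-finite loss at epoch {epoch}, tile {X[i].tile}"
                        )
                    total = loss if total is None else total + loss
                (total / float(len(batch))).backward()
                if self.grad_clip > 0:
                    opt.clip_grad_norm(self.grad_clip)
                opt.step()
            self.loss_trace_.append(float(np.mean(losses)))
            if n_val > 0:
                val_loss = float(
                    np.mean([
                        float(as_array(self._bce(self._forward_tile(X[i], params), y[i])))
                        for i in val_idx
                    ])
                )
            else:
                val_loss = self.loss_trace_[-1]
            if self.verbose:
                print(f"epoch {epoch}: train {self.loss_trace_[-1]:.4f} val {val_loss:.4f}")
            if val_loss < best_val - 1e-4:
                best_val = val_loss
                best_snapshot = {k: params[k].data.copy() for k in names}
                stall = 0
            elif epoch + 1 >= self.min_epochs:
                stall += 1
                if stall >= self.patience:
                    break
        for k in names:
            params[k].data = best_snapshot[k]
        self.params_ = {k: params[k].data.copy() for k in names}
        self.n_iter_ = len(self.loss_trace_)
        return self

    def _np_params(self) -> dict:
        return {k: np.asarray(v) for k, v in self.params_.items()}

    def predict_proba(self, X: list[TileSequence]) -> np.ndarray:
        p = self._np_params()
        probs = np.array([float(as_array(self._forward_tile(seq, p)).ravel()[0]) for seq in X])
        return np.column_stack([1.0 - probs, probs])

    def predict(self, X: list[TileSequence]) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)

    def predict_poi_scores(self, X: list[TileSequence]) -> list[np.ndarray]:
        """Per-venue risk scores (readout applied before pooling), per tile."""
        p = self._np_params()
        return [as_array(self._forward_tile(seq, p, per_node=True)) for seq in X]

    # checkpointing --------------------------------------------------------
    def save(self, path) -> None:
        """Write fitted weights to an .npz checkpoint."""
        import json

        meta = {k: getattr(self, k) for k in self.get_params()}
        np.savez(path, __meta__=np.array([json.dumps(meta)]), **self.params_)

    @classmethod
    def load(cls, path) -> "GraphLSTMTileClassifier":
        import json

        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"][0]))
        model = cls(**meta)
        model.params_ = {k: data[k] for k in data.files if k != "__meta__"}
        model.classes_ = np.array([0, 1])
        return model


@dataclass
class TrainConfig:
    """Run-level configuration mapped onto the estimator and split."""

    epochs: int = 150
    learning_rate: float = 0.02
    seed: int = 0
    train_fraction: float = 0.7
    delta: float = 0.5
    alpha: float = 0.5
    hidden_gcn: int = 32
    gcn_layers: int = 2
    lstm_hidden: int = 16
    heads: int = 1
    batch_size: int = 8
    lr_decay: float = 0.97
    grad_clip: float = 5.0
    patience: int = 20
    min_epochs: int = 30
    val_fraction: float = 0.1
    category_weights_prior: tuple | None = None

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly between 0 and 1")

    def make_estimator(self) -> GraphLSTMTileClassifier:
        return GraphLSTMTileClassifier(
            hidden_gcn=self.hidden_gcn, gcn_layers=self.gcn_layers,
            lstm_hidden=self.lstm_hidden, heads=self.heads,
            delta=self.delta, alpha=self.alpha,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            lr_decay=self.lr_decay, grad_clip=self.grad_clip, epochs=self.epochs,
            patience=self.patience, min_epochs=self.min_epochs,
            val_fraction=self.val_fraction, random_state=self.seed,
        )


def train(sequences: list[TileSequence], labels, config: TrainConfig | None = None
          ) -> GraphLSTMTileClassifier:
    """Fit a fresh classifier on (sequences, labels); thin estimator wrapper."""
    config = config or TrainConfig()
    return config.make_estimator().fit(sequences, labels)
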