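"""Coding/noncoding sequence classification via k-mer co-occurrence networks.

A nucleotide sequence is mapped to an undirected weighted graph whose
nodes are its length-w words (default w=3) and whose edge weights count
adjacent word-pair occurrences along the sequence.  Coding sequences,
whose word usage is constrained by codon bias, concentrate weight on few
recurrent word adjacencies; noncoding sequences of matched composition
spread weight more evenly.  The classifier exploits this by recomputing
six global topological measures while edges below an increasing weight
threshold are stripped away, concatenating the measures over T threshold
iterations into one feature vector, and fitting an information-gain
decision tree (or a small forest of them, the default) on labelled
coding/noncoding training sequences.  RMRJ sequences labelled coding mark
their circRNAs as translated.

Feature vectors are start-codon agnostic by construction: no ORF, ATG or
stop-codon logic enters the features, so translation initiated at
non-AUG codons is not penalised.
"""

from __future__ import annotations

import logging
import pickle
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import MinMaxScaler
from sklearn.tree import DecisionTreeClassifier

log = logging.getLogger(__name__)

DEFAULT_WORD_LEN = 3
DEFAULT_THRESHOLDS = 10
N_MEASURES = 6
MODEL_FORMAT_VERSION = 1

LABEL_CODING = "coding"
LABEL_NONCODING = "noncoding"


# ---------------------------------------------------------------------------
# sequence -> network
# ---------------------------------------------------------------------------

def sequence_to_network(seq: str, w: int = DEFAULT_WORD_LEN) -> nx.Graph:
    """Word-adjacency graph of a sequence.

    Nodes are the distinct N-free words of length w (overlapping, step 1);
    each consecutive word pair adds 1 to the weight of the undirected edge
    between them.  Identical consecutive words would be self-loops and
    contribute nothing.  A sequence shorter than w yields an empty graph.
    """
    g = nx.Graph()
    seq = seq.upper()
    n_words = len(seq) - w + 1
    prev = None
    for i in range(max(0, n_words)):
        word = seq[i:i + w]
        if "N" in word:
            prev = None
            continue
        g.add_node(word)
        if prev is not None and prev != word:
            if g.has_edge(prev, word):
                g[prev][word]["weight"] += 1
            else:
                g.add_edge(prev, word, weight=1)
        prev = word
    return g


def network_measures(g: nx.Graph) -> np.ndarray:
    """Six global topological measures; degenerate cases map to 0.

    Order: mean degree; mean clustering coefficient (degree<2 nodes count
    0); degree assortativity (Pearson over edge endpoint degrees, 0 when
    undefined); mean betweenness centrality normalised by (n-1)(n-2)/2;
    mean unweighted shortest-path length over ordered pairs within the
    largest connected component; edge count / node count.
    """
    n = g.number_of_nodes()
    m = g.number_of_edges()
    if n == 0:
        return np.zeros(N_MEASURES)
    mean_degree = 2.0 * m / n
    mean_clustering = sum(nx.clustering(g).values()) / n if m else 0.0
    if m >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # nan path for zero variance
            assort = nx.degree_assortativity_coefficient(g)
        if not np.isfinite(assort):
            assort = 0.0
    else:
        assort = 0.0
    if n > 2 and m:
        mean_betweenness = sum(nx.betweenness_centrality(g, normalized=True).values()) / n
    else:
        mean_betweenness = 0.0
    if m:
        largest = max(nx.connected_components(g), key=len)
        if len(largest) > 1:
            sub = g.subgraph(largest)
            mean_path = nx.average_shortest_path_length(sub)
        else:
            mean_path = 0.0
    else:
        mean_path = 0.0
    return np.array([mean_degree, mean_clustering, assort,
                     mean_betweenness, mean_path, m / n])


def feature_vector(seq: str, w: int = DEFAULT_WORD_LEN,
                   thresholds: int = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Concatenated measures under iterative edge-weight thresholding.

    Iteration t (t = 0 .. thresholds-1) keeps edges with weight > t on the
    full node set and recomputes the six measures; the edge sets are
    nested, so the vector traces how fast the network's structure decays
    as rare word adjacencies are stripped.  Length = 6 * thresholds.
    """
    if thresholds < 1:
        raise ValueError("thresholds must be >= 1")
    g = sequence_to_network(seq, w)
    out = np.empty(N_MEASURES * thresholds)
    current = g
    for t in range(thresholds):
        if t > 0:
            keep = [(u, v) for u, v, d in current.edges(data=True) if d["weight"] > t]
            pruned = nx.Graph()
            pruned.add_nodes_from(g.nodes)
            pruned.add_edges_from(
                (u, v, current[u][v]) for u, v in keep)
            current = pruned
        out[t * N_MEASURES:(t + 1) * N_MEASURES] = network_measures(current)
    return out


def feature_matrix(seqs: Sequence[str], w: int, thresholds: int) -> np.ndarray:
    return np.vstack([feature_vector(s, w, thresholds) for s in seqs]) \
        if seqs else np.empty((0, N_MEASURES * thresholds))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class CodingModel:
    """Min-max scaling + information-gain tree(s) over network features."""

    w: int
    thresholds: int
    scaler: MinMaxScaler
    estimator: object  # DecisionTreeClassifier or RandomForestClassifier
    classes: tuple[str, str] = (LABEL_CODING, LABEL_NONCODING)
    cv_accuracy: float = float("nan")
    format_version: int = MODEL_FORMAT_VERSION

    def predict(self, seqs: Sequence[str]) -> list[str]:
        labels, _ = self.predict_with_scores(seqs)
        return labels

    def predict_with_scores(self, seqs: Sequence[str]) -> tuple[list[str], np.ndarray]:
        """Labels plus the model's coding-class probability per sequence."""
        labels: list[str] = []
        scores = np.zeros(len(seqs))
        ok_idx = [i for i, s in enumerate(seqs) if len(s) >= self.w + 1]
        short_idx = sorted(set(range(len(seqs))) - set(ok_idx))
        for i in short_idx:
            log.warning("sequence %d shorter than w+1=%d: labelled %s",
                        i, self.w + 1, LABEL_NONCODING)
        pred = {}
        if ok_idx:
            x = feature_matrix([seqs[i] for i in ok_idx], self.w, self.thresholds)
            x = self.scaler.transform(x)
            y = self.estimator.predict(x)
            proba = self.estimator.predict_proba(x)
            coding_col = list(self.estimator.classes_).index(LABEL_CODING)
            for j, i in enumerate(ok_idx):
                pred[i] = (y[j], proba[j, coding_col])
        for i in range(len(seqs)):
            label, score = pred.get(i, (LABEL_NONCODING, 0.0))
            labels.append(str(label))
            scores[i] = score
        return labels, scores

    def save(self, path) -> None:
        header = {
            "format_version": self.format_version,
            "w": self.w,
            "thresholds": self.thresholds,
            "scale_min": self.scaler.data_min_.tolist(),
            "scale_max": self.scaler.data_max_.tolist(),
            "classes": list(self.classes),
            "cv_accuracy": self.cv_accuracy,
        }
        with open(path, "wb") as fh:
            pickle.dump({"header": header, "model": self}, fh, protocol=4)

    @classmethod
    def load(cls, path) -> "CodingModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        model = payload["model"]
        if payload["header"]["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        return model


def train_classifier(
    pos: Sequence[str],
    neg: Sequence[str],
    w: int = DEFAULT_WORD_LEN,
    thresholds: int = DEFAULT_THRESHOLDS,
    cv_folds: int = 5,
    seed: int = 0,
    n_trees: int = 25,
) -> CodingModel:
    """Fit the coding/noncoding classifier on labelled training sequences.

    ``pos`` are coding sequences, ``neg`` noncoding; features are min-max
    scaled to the training bounds and an entropy-split (information gain)
    tree is fitted — a forest of ``n_trees`` such trees by default,
    ``n_trees=1`` for a single tree.  Stratified cross-validation accuracy
    is computed on the training set before the final fit.  Deterministic
    for a fixed seed and input data.
    """
    if not pos or not neg:
        raise ValueError("both coding and noncoding training sets must be non-empty")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    x = feature_matrix(list(pos) + list(neg), w, thresholds)
    y = np.array([LABEL_CODING] * len(pos) + [LABEL_NONCODING] * len(neg))
    scaler = MinMaxScaler().fit(x)
    xs = scaler.transform(x)
    if np.allclose(x[:len(pos)].mean(axis=0), x[len(pos):].mean(axis=0)):
        warnings.warn("degenerate separation: class feature means coincide",
                      stacklevel=2)
    if n_trees <= 1:
        est = DecisionTreeClassifier(criterion="entropy", random_state=seed)
    else:
        est = RandomForestClassifier(
            n_estimators=n_trees, criterion="entropy", random_state=seed)
    cv_folds = min(cv_folds, len(pos), len(neg))
    if cv_folds >= 2:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        cv_acc = float(cross_val_score(est, xs, y, cv=cv).mean())
    else:  # too few examples per class to cross-validate
        cv_acc = float("nan")
    est.fit(xs, y)
    log.info("classifier trained on %d+%d sequences; %d-fold CV accuracy %.3f",
             len(pos), len(neg), cv_folds, cv_acc)
    return CodingModel(w, thresholds, scaler, est, cv_accuracy=cv_acc)


def classify_rmrjs(rmrjs: Sequence, model: CodingModel,
                   full_sequences: dict[str, str] | None = None):
    """Label each RMRJ coding/noncoding; coding RMRJs mark translated circRNAs.

    By default the RMRJ sequence itself is classified; passing
    ``full_sequences`` (circ_id -> monomer sequence) switches to whole-
    circRNA classification.  Returns (records, translated_ids) where each
    record is (circ_id, label, coding score).
    """
    if not rmrjs:
        return [], []
    seqs = []
    for r in rmrjs:
        if full_sequences is not None:
            seqs.append(full_sequences[r.circ_id])
        else:
            seqs.append(r.seq)
    labels, scores = model.predict_with_scores(seqs)
    records = [(r.circ_id, label, float(score))
               for r, label, score in zip(rmrjs, labels, scores)]
    translated = [cid for cid, label, _ in records if label == LABEL_CODING]
    return records, translated
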