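"""Seven-feature matrix assembly, random-forest fitting and probability ranking.

The feature vector of a protein in a given network is
(Den1, Den2, BC, IDC, LC, DOS, SLS): two neighbourhood densities, the
global betweenness, the complex in-degree, the Laplacian centrality, the
degree-augmented orthologous score and the localization score. A forest of
1000 trees (default) is fitted on the pooled labelled rows of the training
networks — one row per (protein, network) pair, never deduplicated — and a
held-out network is ranked by descending predicted essentiality probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import networkx as nx
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import bioscores, topology
from .config import Config
from .graph_io import ComplexCatalog, LocalizationTable, OrthologyTable

FEATURE_COLUMNS = ["den1", "den2", "bc", "idc", "lc", "dos", "sls"]

_MODEL_FORMAT_VERSION = 1

__all__ = [
    "FEATURE_COLUMNS",
    "FittedModel",
    "build_features",
    "train_model",
    "score_and_rank",
    "leave_one_network_out",
]


def build_features(
    net: nx.Graph,
    catalog: ComplexCatalog,
    orthology: OrthologyTable,
    localization: LocalizationTable,
    cfg: Config | None = None,
    essential: set[str] | None = None,
    slc: dict[str, float] | None = None,
) -> pd.DataFrame:
    """One row per network node, columns in ``FEATURE_COLUMNS`` order.

    Missing annotations encode as 0 through the component contracts (a
    protein in no complex has IDC 0, an unlocalized protein has SLS 0, and
    so on), so the matrix never holds missing values. A ``label`` column
    (1 = essential) is appended iff *essential* is given.

    By default the SLC location coefficients behind SLS are computed from
    this network's own LBCC ranking (they are a dataset statistic and never
    see labels); pass *slc* to reuse coefficients computed elsewhere, e.g.
    from training networks only.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot build features for an empty network")
    cfg = cfg or Config()
    d1 = topology.den1(net)
    d2 = topology.den2(net)
    bc = topology.betweenness_centrality(net)
    idc = bioscores.idc(net, catalog)
    lc = topology.laplacian_centrality(net)
    dc = topology.degree_centrality(net)
    osc = bioscores.orthologous_score(net, orthology)
    dosc = bioscores.dos(dc, osc, cfg.dos_scale)
    if slc is None:
        lb = bioscores.lbcc(d1, d2, idc, bc, cfg.log_epsilon)
        slc = bioscores.slc_table(net, localization, lb, cfg.top_fraction_slc)
    slsc = bioscores.sls(localization, slc, net)

    proteins = sorted(net.nodes())
    frame = pd.DataFrame(
        {
            "den1": [d1[v] for v in proteins],
            "den2": [d2[v] for v in proteins],
            "bc": [bc[v] for v in proteins],
            "idc": [idc[v] for v in proteins],
            "lc": [lc[v] for v in proteins],
            "dos": [dosc[v] for v in proteins],
            "sls": [slsc[v] for v in proteins],
        },
        index=pd.Index(proteins, name="protein"),
    )
    if essential is not None:
        frame["label"] = [int(v in essential) for v in proteins]
    return frame


@dataclass
class FittedModel:
    """A fitted forest plus the metadata needed to reuse it safely."""

    classifier: RandomForestClassifier
    columns: list[str]
    rf_seed: int
    n_trees: int
    training_ids: list[str] = field(default_factory=list)

    def save(self, directory: str | Path) -> None:
        """Persist as a binary blob plus a JSON sidecar (config, columns, seed)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.classifier, directory / "model.joblib")
        sidecar = {
            "format_version": _MODEL_FORMAT_VERSION,
            "columns": self.columns,
            "rf_seed": self.rf_seed,
            "n_trees": self.n_trees,
            "training_ids": self.training_ids,
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "FittedModel":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        if sidecar.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {sidecar.get('format_version')}")
        return cls(
            classifier=joblib.load(directory / "model.joblib"),
            columns=sidecar["columns"],
            rf_seed=sidecar["rf_seed"],
            n_trees=sidecar["n_trees"],
            training_ids=sidecar.get("training_ids", []),
        )


def train_model(
    training: list[pd.DataFrame],
    cfg: Config | None = None,
    training_ids: list[str] | None = None,
) -> FittedModel:
    """Fit the forest on the concatenation of labelled feature matrices.

    A protein occurring in several training networks contributes one row per
    network. Raises if any matrix lacks a label column or if the pooled
    labels are single-class.
    """
    if not training:
        raise ValueError("at least one labelled feature matrix is required")
    cfg = cfg or Config()
    for i, frame in enumerate(training):
        if "label" not in frame.columns:
            raise ValueError(f"training matrix {i} has no label column")
        missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"training matrix {i} lacks feature columns {missing}")
    pooled = pd.concat(training, axis=0)
    labels = pooled["label"].to_numpy()
    if len(set(labels.tolist())) < 2:
        raise ValueError("training data contains a single class; both labels are required")
    clf = RandomForestClassifier(
        n_estimators=cfg.rf_trees,
        max_features="sqrt",
        random_state=cfg.rf_seed,
        n_jobs=1,
    )
    clf.fit(pooled[FEATURE_COLUMNS].to_numpy(), labels)
    return FittedModel(
        classifier=clf,
        columns=list(FEATURE_COLUMNS),
        rf_seed=cfg.rf_seed,
        n_trees=cfg.rf_trees,
        training_ids=training_ids or [],
    )


def leave_one_network_out(
    features: dict[str, pd.DataFrame], test_id: str, cfg: Config | None = None
) -> pd.DataFrame:
    """Train on every labelled matrix except *test_id*, rank the held-out one.

    The held-out network's label column (if present) is dropped before
    scoring; only its features reach the model.
    """
    if test_id not in features:
        raise ValueError(f"unknown test network {test_id!r}")
    if len(features) < 2:
        raise ValueError("leave-one-network-out needs at least two networks")
    training_ids = [name for name in features if name != test_id]
    fitted = train_model([features[n] for n in training_ids], cfg, training_ids=training_ids)
    test = features[test_id]
    if "label" in test.columns:
        test = test.drop(columns=["label"])
    return score_and_rank(fitted, test)


def score_and_rank(model: FittedModel, test: pd.DataFrame) -> pd.DataFrame:
    """Probability of essentiality per test protein, ranked.

    Returns a DataFrame with columns ``protein``, ``score``, ``rank`` sorted
    by descending score, ties broken by protein ID ascending; ``rank`` is
    1-based.
    """
    missing = [c for c in model.columns if c not in test.columns]
    if missing:
        raise ValueError(f"test matrix lacks feature columns {missing}")
    proba = model.classifier.predict_proba(test[model.columns].to_numpy())
    class_index = list(model.classifier.classes_).index(1)
    scores = proba[:, class_index]
    ranking = pd.DataFrame({"protein": test.index.to_list(), "score": scores})
    ranking = ranking.sort_values(
        by=["score", "protein"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    ranking["rank"] = ranking.index + 1
    return ranking
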