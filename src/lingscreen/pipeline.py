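"""End-to-end orchestration: corpus -> features -> classifier -> risk flags.

The workflow is: split the corpus; embed all transcripts and fit the SVD
projector on the *training* rows only; extract the four features; z-score
with training statistics; select C by stratified 5-fold CV on the training
split; fit the final L1 logistic model; Platt-calibrate; fix the
high-sensitivity threshold on the development split; report AUC,
sensitivity and specificity on the held-out test split. Everything fitted
(projector, standardizer, C, Platt parameters, threshold) depends only on
the split it is allowed to see, so the test metrics are leakage-free, and
the whole run is a pure function of (corpus, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import embedding as emb
from . import evaluation as ev
from . import model as mdl
from .errors import ConfigError, DataError, ScreeningError
from .features import (
    DepressionLexicon,
    ValenceLexicon,
    default_depression_lexicon,
    default_valence_lexicon,
    load_valence_tsv,
    load_word_list,
    FEATURE_NAMES,
    avg_dependency_distance,
    negative_sentiment,
    negative_word_ratio,
)
from .transcript_io import (
    ParsedSentence,
    SplitSpec,
    Transcript,
    read_conllu,
    read_corpus_jsonl,
    split_dataset,
)

logger = logging.getLogger("lingscreen")

#: Reference train/dev/test proportions (106/35/47 of 188).
SPLIT_FRACTIONS = (106 / 188, 35 / 188, 47 / 188)


@dataclass
class PipelineConfig:
    """Everything a full screening run needs, serializable to/from YAML."""

    corpus_path: Optional[str] = None
    parses_dir: Optional[str] = None
    labels_path: Optional[str] = None
    lexicon_path: Optional[str] = None
    valence_path: Optional[str] = None
    negators_path: Optional[str] = None
    output_dir: Optional[str] = None
    n_train: Optional[int] = None
    n_dev: Optional[int] = None
    n_test: Optional[int] = None
    embedding_backend: str = "hashed"
    embedding_dim: int = 256
    k: int = 8
    component_policy: str = "fixed"  # "fixed" | "correlate"
    component_index: int = 2
    orient_to_labels: bool = True
    c_grid: tuple[float, ...] = mdl.DEFAULT_C_GRID
    cv_folds: int = 5
    target_sensitivity: float = mdl.DEFAULT_TARGET_SENSITIVITY
    calibration_set: str = "dev"  # "dev" | "train"
    negation_window: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_sensitivity <= 1:
            raise ConfigError("target_sensitivity must be in (0, 1]")
        if self.component_policy not in ("fixed", "correlate"):
            raise ConfigError(f"unknown component policy '{self.component_policy}'")
        if self.calibration_set not in ("dev", "train"):
            raise ConfigError(f"unknown calibration set '{self.calibration_set}'")

    def split_spec(self, n: int) -> SplitSpec:
        if self.n_train is not None:
            if self.n_dev is None or self.n_test is None:
                raise ConfigError("give all of n_train/n_dev/n_test or none")
            return SplitSpec(self.n_train, self.n_dev, self.n_test, seed=self._sub_seed(0))
        n_train = int(round(n * SPLIT_FRACTIONS[0]))
        n_dev = int(round(n * SPLIT_FRACTIONS[1]))
        n_test = n - n_train - n_dev
        return SplitSpec(n_train, n_dev, n_test, seed=self._sub_seed(0))

    def _sub_seed(self, index: int) -> int:
        state = np.random.SeedSequence(self.seed).generate_state(4)
        return int(state[index]) % (2**31)


@dataclass
class PipelineResult:
    """Fitted artifacts plus the evaluation report of one full run."""

    model: mdl.CalibratedModel
    projector: emb.SvdProjector
    cv: mdl.CvResult
    features: pd.DataFrame  # id, four features, label, split
    metrics: dict
    splits: dict[str, list[str]]


class _Stage:
    """Context manager tagging any error with the pipeline stage name."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage: %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, ScreeningError):
            exc.args = (f"[stage {self.name}] {exc.args[0] if exc.args else ''}",)
        return False


def _load_lexicons(
    config: PipelineConfig,
) -> tuple[DepressionLexicon, ValenceLexicon]:
    lex = (
        DepressionLexicon(words=load_word_list(config.lexicon_path))
        if config.lexicon_path
        else default_depression_lexicon()
    )
    if config.valence_path:
        negators = (
            load_word_list(config.negators_path)
            if config.negators_path
            else default_valence_lexicon().negators
        )
        vlex = ValenceLexicon(
            valence=load_valence_tsv(config.valence_path),
            negators=negators,
            negation_window=config.negation_window,
        )
    else:
        vlex = default_valence_lexicon(negation_window=config.negation_window)
    return lex, vlex


def _file_hash(path: Optional[str]) -> Optional[str]:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_full_pipeline(
    config: PipelineConfig,
    transcripts: Optional[Sequence[Transcript]] = None,
    parses: Optional[dict[str, list[ParsedSentence]]] = None,
) -> PipelineResult:
    """Execute the whole screening workflow on a labeled corpus.

    The corpus comes either from ``config.corpus_path``/``parses_dir`` or
    directly as in-memory objects. Every transcript must carry a binary
    label and have a parse list. When ``config.output_dir`` is set, the
    model JSON, metrics JSON, feature CSV and run log are written there
    (only after the run succeeds, so a failed run leaves no partial
    outputs).
    """
    with _Stage("load"):
        if transcripts is None:
            if config.corpus_path is None:
                raise ConfigError("no corpus: set corpus_path or pass transcripts")
            transcripts = read_corpus_jsonl(config.corpus_path)
            if config.labels_path:
                lab = pd.read_csv(config.labels_path, dtype={"id": str})
                lmap = dict(zip(lab["id"], lab["label"].astype(int)))
                for t in transcripts:
                    t.label = lmap.get(t.id, t.label)
        if parses is None:
            if config.parses_dir is None:
                raise ConfigError("no parses: set parses_dir or pass parses")
            try:
                parses = {
                    t.id: read_conllu(Path(config.parses_dir) / f"{t.id}.conllu")
                    for t in transcripts
                }
            except FileNotFoundError as exc:
                raise DataError(f"missing parse file: {exc.filename}") from None
        transcripts = list(transcripts)
        unlabeled = [t.id for t in transcripts if t.label is None]
        if unlabeled:
            raise DataError(f"unlabeled transcripts: {unlabeled[:5]}")
        missing = [t.id for t in transcripts if t.id not in parses]
        if missing:
            raise DataError(f"transcripts without parses: {missing[:5]}")
        lex, vlex = _load_lexicons(config)

    with _Stage("split"):
        ids = [t.id for t in transcripts]
        labels = {t.id: int(t.label) for t in transcripts}
        spec = config.split_spec(len(ids))
        train_ids, dev_ids, test_ids = split_dataset(ids, spec, labels=labels)
        by_id = {t.id: t for t in transcripts}

    with _Stage("embed"):
        order = train_ids + dev_ids + test_ids
        texts = [by_id[i].normalized_text for i in order]
        if config.embedding_backend == "hashed":
            E_all = emb.hashed_embedding(
                texts, dim=config.embedding_dim, seed=config._sub_seed(1)
            )
        elif config.embedding_backend == "sentence-transformer":  # pragma: no cover
            E_all = emb.sentence_transformer_embedding(texts)
        else:
            raise ConfigError(f"unknown embedding backend '{config.embedding_backend}'")
        E_all.ids = list(order)
        n_train = len(train_ids)
        E_train = emb.EmbeddingMatrix(rows=E_all.rows[:n_train], ids=list(train_ids))

    with _Stage("fit-projector"):
        y_train = np.array([labels[i] for i in train_ids])
        projector = emb.fit_svd_projector(
            E_train,
            k=config.k,
            component_index=config.component_index,
            backend=config.embedding_backend,
            backend_config={"dim": config.embedding_dim},
        )
        if config.component_policy == "correlate":
            j = emb.select_component(E_train, y_train, projector=projector)
            projector.component_index = j
        if config.orient_to_labels:
            projector = emb.orient_to_labels(projector, E_train, y_train)

    with _Stage("extract-features"):
        emb1_all = emb.project_matrix(E_all, projector)
        rows = []
        for pos, tid in enumerate(order):
            t = by_id[tid]
            toks = t.tokens
            rows.append(
                {
                    "id": tid,
                    "neg_words_r": negative_word_ratio(toks, lex),
                    "emb_1": float(emb1_all[pos]),
                    "sent_neg": negative_sentiment(toks, vlex),
                    "avg_dep_dist": avg_dependency_distance(parses[tid]),
                    "label": labels[tid],
                    "split": (
                        "train" if pos < n_train
                        else "dev" if pos < n_train + len(dev_ids)
                        else "test"
                    ),
                }
            )
        table = pd.DataFrame(rows)

    def _matrix(split: str) -> tuple[np.ndarray, np.ndarray]:
        sub = table[table["split"] == split]
        return sub[list(FEATURE_NAMES)].to_numpy(float), sub["label"].to_numpy(int)

    X_train, y_tr = _matrix("train")
    X_dev, y_dev = _matrix("dev")
    X_test, y_test = _matrix("test")

    with _Stage("standardize"):
        standardizer = mdl.Standardizer.fit(X_train)

    with _Stage("cross-validate"):
        cv = mdl.cv_select_C(
            standardizer.transform(X_train),
            y_tr,
            grid=config.c_grid,
            K=config.cv_folds,
            seed=config._sub_seed(2),
        )

    with _Stage("fit"):
        base = mdl.fit_l1_logistic(standardizer.transform(X_train), y_tr, cv.C_star)
        base.standardizer = standardizer

    with _Stage("calibrate"):
        if config.calibration_set == "dev":
            cal_scores, cal_y = base.raw_scores(X_dev), y_dev
        else:
            cal_scores, cal_y = base.raw_scores(X_train), y_tr
        platt_A, platt_B = mdl.platt_calibrate(cal_scores, cal_y)

    with _Stage("select-threshold"):
        dev_probs = mdl.platt_probability(base.raw_scores(X_dev), platt_A, platt_B)
        threshold = mdl.select_threshold(dev_probs, y_dev, config.target_sensitivity)
        model = mdl.CalibratedModel(
            base=base,
            platt_A=platt_A,
            platt_B=platt_B,
            threshold=threshold,
            target_sensitivity=config.target_sensitivity,
        )

    with _Stage("evaluate"):
        test_scores = base.raw_scores(X_test)
        test_probs, _flags = mdl.predict_risk(model, X_test)
        metrics = {
            "test": ev.metrics_report(test_scores, test_probs, y_test, threshold),
            "dev": ev.operating_point(dev_probs, y_dev, threshold).to_dict(),
            "cv": {"C_star": cv.C_star, "mean_auc_at_C_star": float(np.max(cv.mean_aucs))},
            "n": {"train": len(train_ids), "dev": len(dev_ids), "test": len(test_ids)},
        }
        metrics["dev"]["auc"] = round(ev.roc_auc(base.raw_scores(X_dev), y_dev), 3)

    result = PipelineResult(
        model=model,
        projector=projector,
        cv=cv,
        features=table,
        metrics=metrics,
        splits={"train": train_ids, "dev": dev_ids, "test": test_ids},
    )

    if config.output_dir:
        with _Stage("write"):
            out = Path(config.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            extra = {
                "projector_hash": projector.config_hash(),
                "lexicon_hash": _file_hash(config.lexicon_path),
                "valence_hash": _file_hash(config.valence_path),
                "creation_seed": config.seed,
            }
            model.save(out / "model.json", extra=extra)
            projector.save(out / "projector.json")
            table.to_csv(out / "features.csv", index=False)
            ev.write_metrics(metrics, out / "metrics.json")
            run_log = {
                "config": asdict(config),
                "sub_seeds": {
                    "split": config._sub_seed(0),
                    "embedding": config._sub_seed(1),
                    "cv": config._sub_seed(2),
                },
                "hashes": {
                    "projector": projector.config_hash(),
                    "lexicon": _file_hash(config.lexicon_path),
                    "valence": _file_hash(config.valence_path),
                },
            }
            (out / "run_log.json").write_text(
                json.dumps(run_log, indent=1, default=str), encoding="utf-8"
            )
    return result


def rank_by_component(feature_table: pd.DataFrame, k: int) -> tuple[list[str], list[str]]:
    """Top-k and bottom-k transcript ids by emb_1 (stable tie-break by id).

    Used to inspect what the semantic component responds to: read the
    extreme transcripts side by side.
    """
    if "emb_1" not in feature_table.columns:
        raise ConfigError("feature table has no emb_1 column")
    n = len(feature_table)
    if k > n:
        logger.warning("k=%d larger than table (%d rows); truncating", k, n)
        k = n
    ordered = feature_table.sort_values(
        ["emb_1", "id"], ascending=[False, True], kind="mergesort"
    )
    top = ordered["id"].head(k).tolist()
    bottom = ordered["id"].tail(k).tolist()[::-1]  # ascending emb_1 first
    return top, bottom
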