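"""Config-driven experiment runner.

Reproduces the standard report shapes of a learning-curve study: per-method
curve CSVs, an ALC summary with pairwise significance marks, learning-curve
plots per class scope (all classes vs rare classes), and a manifest that
allows byte-identical re-execution.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus import Corpus, SplitPlan, load_corpus, rare_subset
from .embeddings import EmbeddingTable, load_word2vec_text
from .evaluation import LearningCurve, alc, fisher_randomization_test, run_learning_curves
from .models import ClassifierConfig
from .synthetic import SyntheticConfig, generate_corpus, generate_embeddings

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment"]

_EMBEDDING_KINDS = {"bow_exp", "bow_exp_kg", "cbow", "cbow_kg"}
_KG_KINDS = {"bow_exp_kg", "cbow_kg"}


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative experiment: data source, methods, protocol, comparisons.

    Exactly one of ``corpus_path`` / ``synthetic`` supplies the corpus.  The
    base embedding table feeds ``bow_exp`` and ``cbow``; the knowledge-graph-
    refined table feeds the ``_kg`` variants (for synthetic runs both default
    to the generated table).  ``comparisons`` lists (method, baseline) pairs
    tested one-sided for "method better than baseline" on per-run ALC.
    """

    methods: tuple[str, ...] = ("bow", "bow_exp")
    plan: SplitPlan = field(default_factory=SplitPlan)
    corpus_path: Optional[str] = None
    corpus_format: str = "jsonl"
    synthetic: Optional[SyntheticConfig] = field(default_factory=SyntheticConfig)
    embedding_path: Optional[str] = None
    kg_embedding_path: Optional[str] = None
    rare_threshold: float = 0.0002
    comparisons: tuple[tuple[str, str], ...] = (("bow_exp", "bow"),)
    output_dir: str = "bowexp_out"
    C: float = 1.0
    alc_rule: str = "mean"

    def __post_init__(self) -> None:
        object.__setattr__(self, "methods", tuple(self.methods))
        object.__setattr__(self, "comparisons", tuple(tuple(p) for p in self.comparisons))
        if not self.methods:
            raise ValueError("at least one method is required")
        if self.corpus_path is not None and self.synthetic is not None:
            object.__setattr__(self, "synthetic", None)
        if self.corpus_path is None and self.synthetic is None:
            raise ValueError("either corpus_path or a synthetic config is required")

    def validate(self) -> None:
        """Fail fast — before any training — on unsatisfiable references."""
        for m in self.methods:
            ClassifierConfig(kind=m, C=self.C)  # validates the kind
        for a, b in self.comparisons:
            for m in (a, b):
                if m not in self.methods:
                    raise ValueError(f"comparison references method {m!r} not in methods")
        if self.corpus_path is not None and not Path(self.corpus_path).exists():
            raise FileNotFoundError(self.corpus_path)
        if self.synthetic is None:
            for m in self.methods:
                path = self.kg_embedding_path if m in _KG_KINDS else self.embedding_path
                if m in _EMBEDDING_KINDS and (path is None or not Path(path).exists()):
                    raise FileNotFoundError(
                        f"method {m!r} needs an embedding table; missing file: {path}"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "plan" in raw:
            raw["plan"] = SplitPlan(**raw["plan"])
        if raw.get("synthetic") is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ExperimentReport:
    curves: dict[tuple[str, str], LearningCurve]  # (method, scope) -> curve
    alc_table: pd.DataFrame
    comparisons: pd.DataFrame
    output_dir: Path


def _load_inputs(config: ExperimentConfig):
    if config.synthetic is not None:
        corpus = generate_corpus(config.synthetic)
        needs = [m for m in config.methods if m in _EMBEDDING_KINDS]
        tables: dict[str, EmbeddingTable] = {}
        if needs:
            generated = generate_embeddings(config.synthetic)
            for m in needs:
                tables[m] = generated
    else:
        corpus = load_corpus(config.corpus_path, config.corpus_format)
        tables = {}
        cache: dict[str, EmbeddingTable] = {}
        for m in config.methods:
            if m not in _EMBEDDING_KINDS:
                continue
            path = config.kg_embedding_path if m in _KG_KINDS else config.embedding_path
            if path not in cache:
                cache[path] = load_word2vec_text(path)
            tables[m] = cache[path]
    return corpus, tables


def _plot_scope(curves: dict[tuple[str, str], LearningCurve], scope: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for (method, sc), curve in sorted(curves.items()):
        if sc != scope:
            continue
        ps = np.asarray(curve.proportions)
        mean = curve.mean_curve()
        sd = curve.scores.std(axis=0)
        ax.plot(ps, mean, marker="o", label=method)
        ax.fill_between(ps, mean - sd, mean + sd, alpha=0.15)
    ax.set_xlabel("training proportion")
    ax.set_ylabel("macro-averaged F1")
    ax.set_title(f"Learning curves ({scope} classes)")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_experiment(config: ExperimentConfig, plots: bool = True) -> ExperimentReport:
    """Run every method under the shared split plan and write the report bundle.

    Outputs in ``config.output_dir``: ``curves.csv`` (long format),
    ``alc_summary.csv``, ``comparisons.csv``, one plot per scope, and
    ``manifest.json``.  Because all methods share the plan's splits, the
    randomization tests operate on genuinely paired per-run ALC values.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus, tables = _load_inputs(config)
    logger.info("corpus: %d documents, %d classes", len(corpus), len(corpus.classes))

    rare = rare_subset(corpus, config.rare_threshold)
    scopes: dict[str, object] = {"all": "all"}
    if rare:
        scopes["rare"] = rare
        logger.info("rare scope: %d classes at prevalence <= %g", len(rare), config.rare_threshold)

    curves: dict[tuple[str, str], LearningCurve] = {}
    for method in config.methods:
        cc = ClassifierConfig(kind=method, C=config.C)
        result = run_learning_curves(corpus, cc, config.plan, scopes,
                                     embeddings=tables.get(method))
        for scope_name, curve in result.items():
            curves[(method, scope_name)] = curve
        logger.info("method %s done (ALC all = %.4f)", method, alc(result["all"], config.alc_rule))

    long_df = pd.concat(
        [curves[(m, s)].to_dataframe(method=m).assign(scope=s)
         for m in config.methods for s in scopes],
        ignore_index=True,
    )
    long_df.to_csv(out / "curves.csv", index=False)

    comp_rows = []
    for a, b in config.comparisons:
        for s in scopes:
            pa = curves[(a, s)].scores.mean(axis=1)  # per-run ALC
            pb = curves[(b, s)].scores.mean(axis=1)
            p = fisher_randomization_test(pa, pb, seed=config.plan.seed)
            comp_rows.append({"method": a, "baseline": b, "scope": s,
                              "mean_alc_diff": float(np.mean(pa - pb)),
                              "p_value": p, "significant_at_0.05": p < 0.05})
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["method", "baseline", "scope", "mean_alc_diff", "p_value",
                 "significant_at_0.05"],
    )
    comparisons.to_csv(out / "comparisons.csv", index=False)

    alc_rows = []
    for m in config.methods:
        for s in scopes:
            row = {"method": m, "scope": s, "alc": alc(curves[(m, s)], config.alc_rule)}
            marks = comparisons[(comparisons.method == m) & (comparisons.scope == s)
                                & comparisons["significant_at_0.05"]]
            row["beats"] = ",".join(marks.baseline) if len(marks) else ""
            alc_rows.append(row)
    alc_table = pd.DataFrame(alc_rows)
    alc_table.to_csv(out / "alc_summary.csv", index=False)

    if plots:
        for s in scopes:
            _plot_scope(curves, s, out / f"learning_curve_{s}.png")

    manifest = {
        "bowexp_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "corpus": {"n_documents": len(corpus), "n_classes": len(corpus.classes),
                   "n_rare_classes": len(rare)},
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return ExperimentReport(curves, alc_table, comparisons, out)
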