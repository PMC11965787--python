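"""Diagnostic visualizations: per-subject quality, certainty distribution,
and a label-blind 2-D t-SNE embedding of the feature space.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.manifold import TSNE


@dataclass
class TsneConfig:
    perplexity: float = 30.0
    n_iter: int = 1000
    seed: int = 0


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # (n, 2)
    labels: np.ndarray
    certainty: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "label": self.labels,
                "certainty": self.certainty,
            }
        )


def embed_tsne(
    X: np.ndarray,
    labels,
    certainties,
    cfg: TsneConfig | None = None,
) -> EmbeddingResult:
    """2-D t-SNE of standardized feature vectors; labels are carried along
    for plotting only and never influence the embedding."""
    cfg = cfg or TsneConfig()
    X = np.asarray(X, dtype=float)
    if len(X) < 50:
        raise ValueError(f"need at least 50 recordings to embed, got {len(X)}")
    if len(X) <= 3 * cfg.perplexity:
        raise ValueError(
            f"too few points ({len(X)}) for perplexity {cfg.perplexity}; "
            "reduce perplexity or add recordings"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=cfg.perplexity,
        max_iter=cfg.n_iter,
        random_state=cfg.seed,
        init="pca",
    )
    coords = tsne.fit_transform(X)
    return EmbeddingResult(
        coords=np.asarray(coords, dtype=float),
        labels=np.asarray(labels),
        certainty=np.asarray(certainties, dtype=float),
    )


def plot_embedding(emb: EmbeddingResult, path: str | Path) -> None:
    """Two panels: points colored by rhythm label and by certainty."""
    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    for lab in np.unique(emb.labels):
        m = emb.labels == lab
        axes[0].scatter(emb.coords[m, 0], emb.coords[m, 1], s=6, label=str(lab))
    axes[0].legend(markerscale=2)
    axes[0].set_title("t-SNE by rhythm label")
    sc = axes[1].scatter(
        emb.coords[:, 0], emb.coords[:, 1], c=emb.certainty, s=6, cmap="viridis"
    )
    fig.colorbar(sc, ax=axes[1], label="classification certainty")
    axes[1].set_title("t-SNE by certainty")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_quality_per_subject(manifest: pd.DataFrame, path: str | Path) -> None:
    """Fraction of sufficient-quality recordings for each subject."""
    frac = manifest.groupby("subject_id")["ppg_sufficient"].mean().sort_index()
    fig, ax = plt.subplots(figsize=(max(6, 0.12 * len(frac)), 4))
    ax.bar(range(len(frac)), 100 * frac.to_numpy(), width=0.9)
    ax.set_xlabel("subject")
    ax.set_ylabel("% recordings with sufficient quality")
    ax.set_ylim(0, 105)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_certainty_distribution(
    predictions: pd.DataFrame, path: str | Path, gate: float = 0.9
) -> None:
    """Histogram of classification certainty with the abstention gate marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    cert = predictions["certainty"].dropna()
    ax.hist(cert, bins=np.linspace(0.5, 1.0, 51), log=True)
    ax.axvline(gate, color="red", linestyle="--", label=f"gate = {gate}")
    ax.set_xlabel("classification certainty")
    ax.set_ylabel("recordings")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
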