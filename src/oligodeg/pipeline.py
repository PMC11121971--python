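"""End-to-end reproduction of the structure/biodegradability workflow.

Stages: (1) build the twelve tetramer model structures and check them
against the recorded SMILES; (2) compute the in-house 18-descriptor MIF
matrix; (3) pretreat (zero-variance and ADME-name exclusion); (4) PCA
and K-means on the scores; (5) PLS with leave-one-out Q2, both with the
nitrogen-containing outlier excluded (the published design) and on all
twelve structures; (6) recompute every derivable degradation-degree and
dispersity cell of the measurement tables.

The published PCA percentages and PLS R2/Q2 were obtained with a
commercial descriptor engine whose values are not printed; this
pipeline therefore reports its own multivariate statistics side by side
with the published ones for comparison, and only the arithmetic stages
(structures, Dt, dispersity) are expected to reproduce printed cells.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from oligodeg import chemlib
from oligodeg.chemometrics import (
    DescriptorPretreater,
    PLSRegressorQ2,
    ScaledPCA,
    kmeans_cluster,
)
from oligodeg.fixtures import (
    DEFAULT_CONC,
    OUTLIER_ID,
    PaperFixtures,
    load_fixtures,
    verify_fixture_consistency,
)
from oligodeg.mif import descriptor_matrix

#: Published multivariate statistics, for side-by-side display only --
#: they depend on a proprietary descriptor engine and are not gates.
PUBLISHED_REFERENCE = {
    "pca_explained_pct": [38.9, 23.8, 15.6],
    "pls_r2": 0.98,
    "pls_q2": 0.57,
    "pls_n_lv": 5,
}


@dataclass
class ReproductionConfig:
    spacing: float = 0.5  # grid spacing, Angstrom
    margin: float = 5.0  # grid margin, Angstrom
    seed: int = 20240516
    n_pca_components: int = 2
    kmeans_k: int = 3  # two clusters + one outlier
    n_lv: int = 5
    scale: str = "autoscale"
    conc: float = DEFAULT_CONC
    use_printed_smiles: bool = True  # descriptors from the recorded strings


@dataclass
class RunReport:
    config: dict
    structure_matches: int
    structure_mismatches: list[str]
    pretreat_dropped: list[str]
    pca_explained_pct: list[float]
    cluster_labels: dict[str, int]
    outlier_is_singleton: bool
    pls: dict  # outlier-excluded model
    pls_all12: dict
    dt_verification_counts: dict[str, int]
    published_reference: dict = field(default_factory=lambda: dict(PUBLISHED_REFERENCE))

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, **kwargs)


def build_and_check_structures(fixtures: PaperFixtures) -> tuple[pd.DataFrame, list[str]]:
    """Build each tetramer from its unit sequence; compare to the record."""
    rows, mismatches = [], []
    for _, row in fixtures.tetramers.iterrows():
        seq = chemlib.OligomerSequence(
            tuple(row["units"].split(";")), linkage=row["linkage"]
        )
        built = chemlib.build_oligomer(seq)
        same = chemlib.structures_equal(built.smiles, row["smiles_printed"])
        if not same:
            mismatches.append(row["label"])
        rows.append(
            {
                "label": row["label"],
                "smiles_built": built.smiles,
                "smiles_printed": row["smiles_printed"],
                "canonical_match": same,
                "avg_mass": built.avg_mass,
                "biodegradation_pct": row["biodegradation_pct"],
            }
        )
    return pd.DataFrame(rows).set_index("label"), mismatches


def _pls_summary(X: pd.DataFrame, y: np.ndarray, n_lv: int, scale: str) -> dict:
    est = PLSRegressorQ2(n_lv=n_lv, scale=scale).fit(X, y).cross_validate(X, y)
    model = est.model_()
    return {
        "n_samples": int(len(X)),
        "n_descriptors": int(X.shape[1]),
        "n_lv": model.n_lv,
        "R2": round(model.R2, 4),
        "Q2": round(model.Q2, 4),
        "PRESS": round(model.PRESS, 4),
        "coefficients": {k: round(v, 6) for k, v in model.coefficients.items()},
    }


def run_paper_reproduction(
    config: ReproductionConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Execute the full workflow; deterministic for a fixed config/seed."""
    cfg = config or ReproductionConfig()
    fixtures = load_fixtures()

    structures, mismatches = build_and_check_structures(fixtures)
    smiles_col = "smiles_printed" if cfg.use_printed_smiles else "smiles_built"
    smiles = structures[smiles_col]

    X18 = descriptor_matrix(
        smiles.tolist(),
        ids=smiles.index.tolist(),
        spacing=cfg.spacing,
        margin=cfg.margin,
        seed=cfg.seed,
    )
    if X18.isna().any().any():
        raise RuntimeError("descriptor stage produced NaN values")

    pre = DescriptorPretreater(exclude=fixtures.adme_exclusions).fit(X18)
    X = pre.transform(X18)

    pca = ScaledPCA(n_components=cfg.n_pca_components, scale=cfg.scale).fit(X)
    clusters = kmeans_cluster(pca.scores_, k=cfg.kmeans_k, seed=cfg.seed % 2**31)
    labels = dict(zip(X.index.astype(str), (int(v) for v in clusters.labels)))
    outlier_label = labels[OUTLIER_ID]
    outlier_singleton = sum(v == outlier_label for v in labels.values()) == 1

    y = structures["biodegradation_pct"].astype(float)
    keep = X.index != OUTLIER_ID
    X_pls_full = X18.loc[keep]
    pre_pls = DescriptorPretreater(exclude=fixtures.adme_exclusions).fit(X_pls_full)
    X_pls = pre_pls.transform(X_pls_full)
    pls = _pls_summary(X_pls, y[keep].values, cfg.n_lv, cfg.scale)
    pls_all = _pls_summary(X, y.values, cfg.n_lv, cfg.scale)

    consistency = verify_fixture_consistency(fixtures, conc=cfg.conc)
    counts = consistency["status"].value_counts().to_dict()

    report = RunReport(
        config=asdict(cfg),
        structure_matches=int(structures["canonical_match"].sum()),
        structure_mismatches=mismatches,
        pretreat_dropped=pre.dropped_zero_variance_ + pre.dropped_excluded_,
        pca_explained_pct=[round(float(v), 2) for v in pca.explained_pct_],
        cluster_labels=labels,
        outlier_is_singleton=bool(outlier_singleton),
        pls=pls,
        pls_all12=pls_all,
        dt_verification_counts={k: int(v) for k, v in counts.items()},
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        X18.to_csv(out / "descriptors.csv")
        structures.to_csv(out / "structures.csv")
        consistency.to_csv(out / "dt_verification.csv", index=False)
        pd.DataFrame(pca.scores_, index=X.index,
                     columns=[f"PC{i+1}" for i in range(cfg.n_pca_components)]
                     ).to_csv(out / "pca_scores.csv")
        (out / "report.json").write_text(report.to_json())
    return report
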