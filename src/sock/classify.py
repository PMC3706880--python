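"""Decision rules and the end-to-end classification pipeline.

A component is called **Artifact** when any of five rules fires, and
**UnlikelyArtifact** otherwise:

========  ==========  =============  ============  =====
rule      smoothness  edge activity  CSF activity  TFN
========  ==========  =============  ============  =====
R1        Unsmooth    any            any           any
R2        Subsmooth   any            any           High
R3        Smooth      High           High          any
R4        any         >= 50% of active volume in edge mask
R5        any         >= 30% of active volume in CSF mask
========  ==========  =============  ============  =====

Edge and TFN High/Low labels come from adaptive 2-means over all
components; the CSF label uses a fixed threshold (High when the CSF
activity is 10% or greater).  R4/R5 are unconditional hard rules on the
voxel-wise overlap fractions.  Every firing rule is recorded per
component, so each verdict carries its provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sock import clustering, features as feat
from sock.clustering import HIGH, LOW, SMOOTH, SUBSMOOTH, UNSMOOTH
from sock.ica_io import ICADecomposition, MaskSet, SockInputError, read_melodic_dir, read_masks, write_report

logger = logging.getLogger("sock")

RULE_NAMES = ["R1_unsmooth", "R2_subsmooth_highTFN", "R3_smooth_edge_csf", "R4_edge50", "R5_csf30"]

ARTIFACT = "Artifact"
UNLIKELY_ARTIFACT = "UnlikelyArtifact"

FEATURE_NAMES = frozenset({"smoothness", "edge", "csf", "tfn"})

#: Columns a rule needs, by feature.
_FEATURE_COLUMNS = {
    "smoothness": ["smoothness"],
    "edge": ["edge_activity", "edge_label", "edge_fraction"],
    "csf": ["csf_activity", "csf_label", "csf_fraction"],
    "tfn": ["tfn", "tfn_label"],
}


@dataclass
class SockConfig:
    """All tunable parameters of the pipeline, with field defaults.

    ``disabled_features`` names features to skip entirely; a rule that
    depends on a disabled feature can never fire.
    """

    seed: int = 0
    n_radii: int = 20
    connectivity: int = 26
    tfn_cutoff_hz: float = 0.08
    csf_label_threshold: float = 0.10
    edge_hard_threshold: float = 0.50
    csf_hard_threshold: float = 0.30
    disabled_features: frozenset = frozenset()

    def __post_init__(self) -> None:
        unknown = set(self.disabled_features) - FEATURE_NAMES
        if unknown:
            raise SockInputError(f"unknown feature names {sorted(unknown)}; valid: {sorted(FEATURE_NAMES)}")
        self.disabled_features = frozenset(self.disabled_features)


@dataclass
class ClassificationReport:
    """Per-component verdicts with triggering rules, plus summary counts."""

    table: pd.DataFrame
    summary: dict

    @property
    def verdicts(self) -> np.ndarray:
        return self.table["verdict"].to_numpy()


def build_feature_table(
    decomposition: ICADecomposition, masks: MaskSet, config: SockConfig | None = None
) -> pd.DataFrame:
    """Compute all features and adaptive labels for every component."""
    config = config or SockConfig()
    n = decomposition.n_components
    disabled = config.disabled_features
    table = pd.DataFrame({"component": np.arange(1, n + 1)})

    if "smoothness" not in disabled:
        curves = feat.compute_ratio_curves(decomposition, n_radii=config.n_radii)
        table["smoothness"] = clustering.cluster_smoothness(curves, seed=config.seed).labels
        logger.info("smoothness labels: %s", dict(zip(*np.unique(table["smoothness"], return_counts=True))))
    else:
        table["smoothness"] = None

    for name, mask in (("edge", masks.edge), ("csf", masks.csf)):
        if name in disabled:
            table[f"{name}_activity"] = np.nan
            table[f"{name}_label"] = None
            table[f"{name}_fraction"] = np.nan
            continue
        overlaps = [
            feat.compute_overlap_feature(
                decomposition.thresholded_maps[..., i], mask, connectivity=config.connectivity
            )
            for i in range(n)
        ]
        table[f"{name}_activity"] = [o.activity for o in overlaps]
        table[f"{name}_fraction"] = [o.overlap_fraction for o in overlaps]
        logger.info(
            "%s activity: min %.3g, median %.3g, max %.3g",
            name, table[f"{name}_activity"].min(),
            table[f"{name}_activity"].median(), table[f"{name}_activity"].max(),
        )

    if "edge" not in disabled:
        table["edge_label"] = clustering.cluster_binary(
            table["edge_activity"].to_numpy(), "edge_activity", seed=config.seed
        ).labels
    if "csf" not in disabled:
        # fixed threshold, no clustering: >= 10% of mask volume is High
        table["csf_label"] = np.where(
            table["csf_activity"].to_numpy() >= config.csf_label_threshold, HIGH, LOW
        )

    if "tfn" not in disabled:
        if decomposition.power_spectra.shape[0] == 0:
            raise SockInputError(
                "temporal-frequency feature is enabled but the decomposition has no power spectra"
            )
        tfns = [
            feat.compute_tfn(
                decomposition.power_spectra[:, i],
                decomposition.tr_seconds,
                cutoff_hz=config.tfn_cutoff_hz,
            ).tfn
            for i in range(n)
        ]
        table["tfn"] = tfns
        table["tfn_label"] = clustering.cluster_binary(
            np.asarray(tfns), "tfn", seed=config.seed
        ).labels
    else:
        table["tfn"] = np.nan
        table["tfn_label"] = None

    return table


def _require(table: pd.DataFrame, feature: str, disabled: frozenset) -> bool:
    """True if the feature is usable; fatal if enabled but missing."""
    if feature in disabled:
        return False
    for col in _FEATURE_COLUMNS[feature]:
        if col not in table.columns:
            raise SockInputError(f"feature table lacks column '{col}' required by feature '{feature}'")
        missing = table[col].isna() if table[col].dtype != object else table[col].isnull()
        if missing.any():
            ic = int(table.loc[missing.idxmax(), "component"]) if "component" in table else int(missing.idxmax()) + 1
            raise SockInputError(f"component {ic} is missing enabled feature '{feature}' (column '{col}')")
    return True


def apply_rules(
    features_table: pd.DataFrame,
    edge_hard_threshold: float = 0.50,
    csf_hard_threshold: float = 0.30,
    disabled_features: frozenset = frozenset(),
) -> ClassificationReport:
    """Apply the decision table; Artifact iff at least one rule fires.

    Boundary comparisons are inclusive ("X% or greater").  All firing
    rules are recorded per component.
    """
    t = features_table
    n = len(t)
    disabled = frozenset(disabled_features)

    has_smooth = _require(t, "smoothness", disabled)
    has_edge = _require(t, "edge", disabled)
    has_csf = _require(t, "csf", disabled)
    has_tfn = _require(t, "tfn", disabled)

    false_col = np.zeros(n, dtype=bool)
    smoothness = t["smoothness"].to_numpy() if has_smooth else None
    fires = {
        "R1_unsmooth": (smoothness == UNSMOOTH) if has_smooth else false_col,
        "R2_subsmooth_highTFN": (
            (smoothness == SUBSMOOTH) & (t["tfn_label"].to_numpy() == HIGH)
            if has_smooth and has_tfn
            else false_col
        ),
        "R3_smooth_edge_csf": (
            (smoothness == SMOOTH)
            & (t["edge_label"].to_numpy() == HIGH)
            & (t["csf_label"].to_numpy() == HIGH)
            if has_smooth and has_edge and has_csf
            else false_col
        ),
        "R4_edge50": (t["edge_fraction"].to_numpy() >= edge_hard_threshold) if has_edge else false_col,
        "R5_csf30": (t["csf_fraction"].to_numpy() >= csf_hard_threshold) if has_csf else false_col,
    }

    triggered = [[r for r in RULE_NAMES if fires[r][i]] for i in range(n)]
    verdicts = np.where([len(tr) > 0 for tr in triggered], ARTIFACT, UNLIKELY_ARTIFACT)

    table = t.copy()
    table["verdict"] = verdicts
    table["triggered_rules"] = triggered
    summary = {
        "n_components": n,
        "artifact": int((verdicts == ARTIFACT).sum()),
        "unlikely_artifact": int((verdicts == UNLIKELY_ARTIFACT).sum()),
        "rule_counts": {r: int(fires[r].sum()) for r in RULE_NAMES},
    }
    logger.info("verdicts: %d Artifact / %d UnlikelyArtifact of %d",
                summary["artifact"], summary["unlikely_artifact"], n)
    return ClassificationReport(table=table, summary=summary)


def run_sock(
    decomposition,
    masks,
    config: SockConfig | None = None,
    *,
    tr_seconds: float | None = None,
    out_path: str | None = None,
) -> ClassificationReport:
    """End-to-end pipeline: load, featurize, label, classify, write.

    Parameters
    ----------
    decomposition : ICADecomposition or str
        In-memory decomposition or a MELODIC-style directory path
        (``tr_seconds`` is then required).
    masks : MaskSet or (edge_path, csf_path)
        In-memory masks or paths to the two NIfTI mask images.
    out_path : str, optional
        When given, the TSV report (and JSON summary) are written there.
    """
    config = config or SockConfig()
    if isinstance(decomposition, str):
        if tr_seconds is None:
            raise SockInputError("tr_seconds is required when reading a decomposition directory")
        decomposition = read_melodic_dir(
            decomposition, tr_seconds, require_spectra="tfn" not in config.disabled_features
        )
    logger.info("decomposition: %d components on grid %s", decomposition.n_components,
                decomposition.grid_shape)
    if not isinstance(masks, MaskSet):
        edge_path, csf_path = masks
        masks = read_masks(edge_path, csf_path, decomposition)

    table = build_feature_table(decomposition, masks, config)
    report = apply_rules(
        table,
        edge_hard_threshold=config.edge_hard_threshold,
        csf_hard_threshold=config.csf_hard_threshold,
        disabled_features=config.disabled_features,
    )
    if out_path is not None:
        write_report(report, out_path)
    return report
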