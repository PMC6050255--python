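"""Probe quality filtering and the beta -> M-value transform.

Probes are excluded when they interrogate or contain a SNP, are known to be
cross-reactive, or fail detection in more than ``max_failed_samples`` samples
(detection p-value above threshold).  Beta values (methylation fractions) are
mapped to M-values, the base-2 logit scale on which variance is approximately
constant and linear modelling is appropriate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MethylationMatrix
from .errors import ConfigurationError, PipelineError

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-reason removal counts (a probe failing several rules counts once
    per reason but is removed once)."""

    n_input: int
    n_retained: int
    removed_snp: int
    removed_crossreactive: int
    removed_detection: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reason": ["snp", "crossreactive", "detection", "total_removed", "retained"],
                "count": [
                    self.removed_snp,
                    self.removed_crossreactive,
                    self.removed_detection,
                    self.n_removed,
                    self.n_retained,
                ],
            }
        )


def filter_probes(
    matrix: MethylationMatrix,
    manifest: pd.DataFrame,
    max_failed_samples: int = 0,
    detection_threshold: float = 0.01,
) -> tuple[MethylationMatrix, FilterReport]:
    """Drop flagged and detection-failing probes, preserving probe order."""
    if not 0.0 < detection_threshold < 1.0:
        raise ConfigurationError("detection_threshold must lie in (0, 1)")
    if max_failed_samples < 0:
        raise ConfigurationError("max_failed_samples must be >= 0")
    man = manifest.set_index("probe_id").loc[matrix.probe_ids]
    snp = man["snp_flag"].to_numpy(bool)
    xr = man["crossreactive_flag"].to_numpy(bool)
    n_failed = (matrix.detection_p.to_numpy() > detection_threshold).sum(axis=1)
    det = n_failed > max_failed_samples
    drop = snp | xr | det
    report = FilterReport(
        n_input=len(drop),
        n_retained=int((~drop).sum()),
        removed_snp=int(snp.sum()),
        removed_crossreactive=int(xr.sum()),
        removed_detection=int(det.sum()),
    )
    if report.n_retained == 0:
        raise PipelineError(f"no probes survive filtering: {report.to_frame().to_dict('records')}")
    keep = ~drop
    filtered = MethylationMatrix(
        beta=matrix.beta.loc[keep], detection_p=matrix.detection_p.loc[keep]
    )
    log.info(
        "filter_probes: %d/%d retained (snp=%d, crossreactive=%d, detection=%d)",
        report.n_retained,
        report.n_input,
        report.removed_snp,
        report.removed_crossreactive,
        report.removed_detection,
    )
    return filtered, report


def beta_to_m(matrix: MethylationMatrix | pd.DataFrame, epsilon: float = 1e-6) -> pd.DataFrame:
    """M = log2(b / (1 - b)) with betas clamped into [epsilon, 1 - epsilon].

    Strictly monotone in beta; clamping keeps boundary values finite without
    changing the matrix shape.
    """
    if not 0.0 < epsilon < 0.5:
        raise ConfigurationError("epsilon must lie in (0, 0.5)")
    beta = matrix.beta if isinstance(matrix, MethylationMatrix) else matrix
    b = np.clip(beta.to_numpy(float), epsilon, 1.0 - epsilon)
    return pd.DataFrame(np.log2(b / (1.0 - b)), index=beta.index, columns=beta.columns)
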