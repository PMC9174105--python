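"""Run configuration: thresholds, seeds and unit conversions shared across stages."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Analysis-wide tunables.

    Attributes
    ----------
    prevalence_threshold:
        Minimum fraction of participants in which a genus must be detected
        (abundance > 0) to be retained. Default 0.10.
    alpha:
        Nominal significance level used e.g. for signed-panel admission.
    fdr_q:
        Benjamini-Hochberg FDR threshold used to flag discoveries.
    n_permutations:
        Permutations for the community-level PERMANOVA test.
    cv_folds:
        Folds for cross-validated diet prediction.
    n_classifier_repeats:
        Reseeded repetitions of the leave-one-province-out classifier cycle.
    random_seed:
        Global seed; stage seeds are derived from it (see :mod:`gutglyc.pipeline`).
    insulin_conversion:
        pmol/l per uU/ml used to convert fasting insulin into the classical
        HOMA-IR formula (which expects uU/ml). Default 6.945.
    carriage_threshold:
        Relative abundance strictly above which a genus counts as "carried"
        when scoring the HMI. Default 0.0 (any detection).
    renormalize_abundance:
        If True, abundance rows are renormalized to sum 1 at read time;
        default is to validate only.
    clr_transform:
        Sensitivity option: use centred log-ratio transformed abundances
        instead of standardized relative abundances in association models.
    robust_poisson_se:
        Use sandwich (HC1) standard errors in the Poisson risk model.
    age_cutpoint, bmi_cutpoint:
        Subgroup boundaries (years; kg/m^2 - 24 is the Chinese overweight
        threshold).
    """

    prevalence_threshold: float = 0.10
    alpha: float = 0.05
    fdr_q: float = 0.05
    n_permutations: int = 1000
    cv_folds: int = 10
    n_classifier_repeats: int = 10
    random_seed: int = 0
    insulin_conversion: float = 6.945
    carriage_threshold: float = 0.0
    renormalize_abundance: bool = False
    clr_transform: bool = False
    robust_poisson_se: bool = True
    age_cutpoint: float = 50.0
    bmi_cutpoint: float = 24.0
    lgbm_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_threshold < 1.0:
            raise ValueError("prevalence_threshold must be in (0, 1)")
        for name in ("n_permutations", "cv_folds", "n_classifier_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.insulin_conversion <= 0:
            raise ValueError("insulin_conversion must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON (by extension)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**(data or {}))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
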