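"""Linear gene-signature models and their on-disk configuration formats.

A signature is a weighted sum over a fixed gene list with a score threshold
that dichotomizes samples into low/high risk, plus an optional affine
correction mapping scores from a newer preprocessing pipeline back onto the
scale the threshold was defined on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError

__all__ = ["SignatureModel", "load_signature", "load_signature_dir"]


@dataclass(frozen=True)
class SignatureModel:
    """A named linear gene signature.

    Parameters
    ----------
    name : str
        Label used in reports.
    genes : tuple of str
        Ordered, unique gene identifiers (matched case-sensitively).
    weights : tuple of float
        One coefficient per gene, in score units per expression unit.
    risk_threshold : float
        Corrected-score cutoff; a sample is high risk iff its score is
        strictly greater than this value.
    batch_slope, batch_intercept : float
        Affine map applied to raw scores (defaults: identity).
    min_coverage : float
        Minimum fraction of signature genes that must be present in a
        cohort before scoring is allowed.
    """

    name: str
    genes: tuple
    weights: tuple
    risk_threshold: float
    batch_slope: float = 1.0
    batch_intercept: float = 0.0
    min_coverage: float = 0.75

    def __post_init__(self):
        genes = tuple(str(g) for g in self.genes)
        weights = tuple(float(w) for w in self.weights)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "weights", weights)
        if len(genes) == 0:
            raise ValidationError("signature must contain at least one gene")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValidationError(f"duplicate signature genes: {dupes}")
        if len(weights) != len(genes):
            raise ValidationError(
                f"{len(weights)} weights for {len(genes)} genes"
            )
        if not all(math.isfinite(w) for w in weights):
            raise ValidationError("signature weights must be finite")
        if not math.isfinite(self.risk_threshold):
            raise ValidationError("risk_threshold must be finite")
        if not math.isfinite(self.batch_slope):
            raise ValidationError("batch_slope must be finite")
        if not math.isfinite(self.batch_intercept):
            raise ValidationError("batch_intercept must be finite")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValidationError("min_coverage must lie in [0, 1]")

    @property
    def weight_map(self) -> dict:
        return dict(zip(self.genes, self.weights))

    @property
    def size(self) -> int:
        return len(self.genes)

    def correct(self, raw):
        """Apply the affine batch correction to raw scores."""
        if self.batch_slope == 0:
            raise ValidationError("batch_slope must be nonzero")
        return self.batch_slope * np.asarray(raw, dtype=float) + self.batch_intercept

    def uncorrect(self, corrected):
        """Invert :meth:`correct` (affine bijection)."""
        if self.batch_slope == 0:
            raise ValidationError("batch_slope must be nonzero")
        return (np.asarray(corrected, dtype=float) - self.batch_intercept) / self.batch_slope


def _from_mapping(data: dict, name: str | None = None) -> SignatureModel:
    genes_field = data.get("genes")
    if genes_field is None:
        raise ValidationError("signature config missing 'genes'")
    if isinstance(genes_field, dict):
        genes = list(genes_field.keys())
        weights = [genes_field[g] for g in genes]
    else:  # list of {gene, weight} or [gene, weight] pairs
        genes, weights = [], []
        for item in genes_field:
            if isinstance(item, dict):
                genes.append(item["gene"])
                weights.append(item["weight"])
            else:
                g, w = item
                genes.append(g)
                weights.append(w)
    threshold = data.get("risk_threshold", data.get("threshold"))
    if threshold is None:
        raise ValidationError("signature config missing 'risk_threshold'")
    return SignatureModel(
        name=name or data.get("name", "signature"),
        genes=tuple(genes),
        weights=tuple(weights),
        risk_threshold=float(threshold),
        batch_slope=float(data.get("batch_slope", 1.0)),
        batch_intercept=float(data.get("batch_intercept", 0.0)),
        min_coverage=float(data.get("min_coverage", 0.75)),
    )


def load_signature(path, *, name: str | None = None, **overrides) -> SignatureModel:
    """Load a signature from YAML, or from a two-column gene/weight TSV.

    For TSV input, scalar fields (``name``, ``risk_threshold``, ...) are
    supplied via keyword overrides.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml", ".json"}:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: expected a mapping at top level")
        data.update(overrides)
        return _from_mapping(data, name=name)
    # two-column TSV: gene<TAB>weight, optional header
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    if table.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (gene, weight)")
    first = table.iloc[0]
    try:
        float(first[1])
    except (TypeError, ValueError):
        table = table.iloc[1:]
    data = {
        "genes": {str(g): float(w) for g, w in zip(table[0], table[1])},
        "name": name or path.stem,
    }
    data.update(overrides)
    return _from_mapping(data, name=name)


def load_signature_dir(directory) -> list:
    """Load every ``*.yaml``/``*.yml`` signature config in a directory."""
    directory = Path(directory)
    sigs = []
    for path in sorted(directory.glob("*.y*ml")):
        sigs.append(load_signature(path))
    if not sigs:
        raise ValidationError(f"no signature configs found in {directory}")
    return sigs
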