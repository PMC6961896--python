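"""Named, ordered registry of the 730 radiomic features.

Features are computed per channel (the normalized ROI plus the four
single-level wavelet subbands) as 14 first-order statistics, 22 GLCM
statistics at each of 4 angles and 11 GLRLM statistics at each of 4
angles: 5 x (14 + 22*4 + 11*4) = 730.  Names follow
``<channel>_<family>_<statistic>[_<angle>]``, e.g.
``LH_glcm_contrast_45``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib

CHANNELS = ("orig", "LL", "LH", "HL", "HH")
ANGLES = (0, 45, 90, 135)

FIRST_ORDER_STATS = (
    "mean",
    "variance",
    "std",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "minimum",
    "maximum",
    "median",
    "range",
    "rms",
    "mad",
    "uniformity",
)

GLCM_STATS = (
    "autocorrelation",
    "contrast",
    "correlation",
    "cluster_prominence",
    "cluster_shade",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "idm",
    "max_probability",
    "sum_of_squares",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "idn",
    "idmn",
    "marginal_mean",
)

GLRLM_STATS = (
    "sre",
    "lre",
    "gln",
    "rln",
    "rp",
    "lgre",
    "hgre",
    "srlge",
    "srhge",
    "lrlge",
    "lrhge",
)


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered feature-name list shared by extraction and modelling."""

    channels: tuple[str, ...] = CHANNELS
    angles: tuple[int, ...] = ANGLES
    names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        names: list[str] = []
        for ch in self.channels:
            for stat in FIRST_ORDER_STATS:
                names.append(f"{ch}_firstorder_{stat}")
            for stat in GLCM_STATS:
                for ang in self.angles:
                    names.append(f"{ch}_glcm_{stat}_{ang}")
            for stat in GLRLM_STATS:
                for ang in self.angles:
                    names.append(f"{ch}_glrlm_{stat}_{ang}")
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in registry")
        object.__setattr__(self, "names", tuple(names))

    def __len__(self) -> int:
        return len(self.names)

    def hash(self) -> str:
        """Short content hash, recorded in output sidecars for provenance."""
        return hashlib.sha256("\n".join(self.names).encode()).hexdigest()[:12]


DEFAULT_REGISTRY = FeatureRegistry()

# the default configuration must yield exactly the 730-feature panel
assert len(DEFAULT_REGISTRY) == 730
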