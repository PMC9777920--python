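"""Pipeline configuration: one object carrying every tunable, with YAML
(de)serialization. The shipped defaults reproduce the calibrated class
thresholds, area rules and density model; ``data/default.yaml`` is the
same configuration in file form for users who prefer editing YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .classification import ClassifierConfig, ClassSpec
from .enhancement import MsrcrParams
from .evaluation import ContentModel

__all__ = ["PipelineConfig", "load_config", "save_config", "default_config_path"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs: classifier (which embeds the
    MSRCR parameters and class specs) and the impurity-content model."""

    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    content: ContentModel = field(default_factory=ContentModel)

    def to_dict(self) -> dict:
        m = self.classifier.msrcr
        return {
            "msrcr": {
                "scales": [float(s) for s in m.scales],
                "weights": [float(w) for w in m.weights],
                "alpha": m.alpha,
                "beta": m.beta,
                "clip_low": m.clip_low,
                "clip_high": m.clip_high,
                "epsilon": m.epsilon,
            },
            "classifier": {
                "source": self.classifier.source,
                "enhance": self.classifier.enhance,
                "priority": list(self.classifier.priority),
                "classes": {
                    s.name: {
                        "h_range": [s.h_range[0], s.h_range[1]],
                        "s_range": [s.s_range[0], s.s_range[1]],
                        "open_radius": s.open_radius,
                        "close_radius": s.close_radius,
                        "dilate_radius": s.dilate_radius,
                        "median_size": s.median_size,
                        "area_rule": list(s.area_rule) if s.area_rule else None,
                    }
                    for s in self.classifier.specs
                },
            },
            "content": {"rho_w": self.content.rho_w, "rho_z": self.content.rho_z},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        m = data.get("msrcr", {})
        msrcr = MsrcrParams(
            scales=tuple(m.get("scales", MsrcrParams.scales)),
            weights=tuple(m.get("weights", MsrcrParams.weights)),
            alpha=m.get("alpha", MsrcrParams.alpha),
            beta=m.get("beta", MsrcrParams.beta),
            clip_low=m.get("clip_low", MsrcrParams.clip_low),
            clip_high=m.get("clip_high", MsrcrParams.clip_high),
            epsilon=m.get("epsilon", MsrcrParams.epsilon),
        )
        c = data.get("classifier", {})
        specs = tuple(
            ClassSpec(
                name=name,
                h_range=tuple(cl["h_range"]),
                s_range=tuple(cl["s_range"]),
                open_radius=cl.get("open_radius", 3),
                close_radius=cl.get("close_radius", 5),
                dilate_radius=cl.get("dilate_radius", 3),
                median_size=cl.get("median_size", 5),
                area_rule=tuple(cl["area_rule"]) if cl.get("area_rule") else None,
            )
            for name, cl in c.get("classes", {}).items()
        ) or None
        classifier = ClassifierConfig(
            **({"specs": specs} if specs else {}),
            priority=tuple(c.get("priority", ("stone", "corncob", "bract"))),
            source=c.get("source", "original"),
            enhance=c.get("enhance", True),
            msrcr=msrcr,
        )
        content = ContentModel(**data.get("content", {}))
        return cls(classifier=classifier, content=content)

    def with_enhancement(self, enabled: bool) -> "PipelineConfig":
        return replace(self, classifier=self.classifier.with_enhancement(enabled))


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML pipeline configuration; defaults when *path* is None."""
    if path is None:
        return PipelineConfig()
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def default_config_path() -> Path:
    """Path of the shipped default YAML (useful as an editing template)."""
    return Path(str(resources.files("cornimpurity") / "data" / "default.yaml"))
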