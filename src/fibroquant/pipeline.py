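"""Pipeline configuration and the end-to-end run.

A single JSON-serializable config drives every stage; each output carries
the config hash so any number in a report can be traced to the exact
parameters that produced it.  Runs with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fibroquant.features import FeatureParams, extract_features, render_heatmap
from fibroquant.io import write_image
from fibroquant.response import (
    read_pairs_csv,
    load_fixture_pairs,
    render_response_heatmap,
    summarize_cohort,
)
from fibroquant.segmentation import SegmentationParams, SlideImage, segment_collagen
from fibroquant.stats import anova_tukey, summarize_by_stage
from fibroquant.synth import SyntheticSlide, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("fibroquant")


def _params_to_dict(obj) -> dict:
    d = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, tuple) and len(v) == 2 and isinstance(v[0], np.ndarray):
            v = [list(map(float, x)) for x in v]
        d[f.name] = v
    return d


@dataclass
class PipelineConfig:
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    seed: int = 0
    output_dir: str = "fibroquant_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "segmentation": _params_to_dict(self.segmentation),
            "features": _params_to_dict(self.features),
            "seed": self.seed,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        seg = d.get("segmentation", {})
        if isinstance(seg.get("stain_vectors"), list):
            seg = dict(seg)
            seg["stain_vectors"] = tuple(np.asarray(v, dtype=float) for v in seg["stain_vectors"])
        return cls(
            segmentation=SegmentationParams(**seg),
            features=FeatureParams(**d.get("features", {})),
            seed=int(d.get("seed", 0)),
            output_dir=d.get("output_dir", "fibroquant_out"),
            log_level=d.get("log_level", "INFO"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    @property
    def config_hash(self) -> str:
        """Hash of the computation-affecting parameters (segmentation,
        features, seed); where outputs land or how much is logged does not
        change what was computed."""
        d = self.to_dict()
        d.pop("output_dir")
        d.pop("log_level")
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(
    config: PipelineConfig,
    *,
    synth_n: int = 0,
    synth_profile: list[float] | None = None,
    synth_size: int = 512,
    slides: list[SyntheticSlide] | None = None,
    pairs_csv: str | None = None,
    use_fixture_pairs: bool = False,
    write_heatmaps: bool = False,
) -> dict:
    """Run synth -> segment -> features -> stats -> response and write the
    report bundle into ``config.output_dir``.

    Inputs are either pre-built slides, a synthetic cohort request
    (``synth_n``/``synth_profile``), and/or a paired-biopsy table.  Returns
    the in-memory report dict that was also written to disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    report: dict = {"config_hash": chash, "config": config.to_dict()}

    all_slides: list[SyntheticSlide] = list(slides or [])
    if synth_n > 0:
        profile = synth_profile or [0.026, 0.057, 0.109]
        log.info("stage=synth n=%d profile=%s seed=%d", synth_n, profile, config.seed)
        all_slides.extend(
            generate_cohort(
                synth_n, profile, config.seed, width_px=synth_size, height_px=synth_size
            )
        )

    if all_slides:
        rows = []
        stage_values = []
        for slide in all_slides:
            image = SlideImage(
                pixels=slide.image, um_per_px=slide.spec.um_per_px, slide_id=slide.slide_id
            )
            seg = segment_collagen(image, config.segmentation)
            feats = extract_features(seg, config.features, slide_id=slide.slide_id)
            log.info(
                "stage=features slide=%s eca=%.3f enc=%.4f hash=%s",
                slide.slide_id,
                feats.eca_percent,
                feats.enc,
                chash,
            )
            rows.append({"slide_id": slide.slide_id, **feats.extended})
            stage_values.append(feats.eca_percent)
            if write_heatmaps:
                hm_dir = out / "heatmaps"
                hm_dir.mkdir(exist_ok=True)
                hm = render_heatmap(
                    image,
                    feats.roi_maps.grids["collagen_fraction"],
                    feature_name="collagen_fraction",
                    roi_px=config.features.roi_px,
                )
                hm.save(hm_dir / f"{slide.slide_id}_eca.png")
        features_df = pd.DataFrame(rows)
        features_path = out / "features.csv"
        with open(features_path, "w", newline="") as fh:
            fh.write(f"# fibroquant features config_hash={chash}\n")
            features_df.to_csv(fh, index=False, float_format="%.10g")
        report["features_csv"] = str(features_path)
        report["n_slides"] = len(all_slides)

        # Stage-wise descriptive stats over the synthetic cohort, using the
        # slides' true-fraction tertiles as pseudo-stages when >= 6 slides.
        if len(all_slides) >= 6:
            fracs = np.array([s.true_collagen_fraction for s in all_slides])
            tertiles = np.quantile(fracs, [1 / 3, 2 / 3])
            pseudo = np.digitize(fracs, tertiles)
            groups = [("F2", "F3", "F4")[k] for k in pseudo]
            if min(np.bincount(pseudo, minlength=3)) >= 2:
                res = anova_tukey(stage_values, groups)
                summaries = summarize_by_stage(stage_values, groups)
                report["stage_anova"] = {
                    "f": res.f,
                    "p": res.p,
                    "tukey": res.tukey.to_dict(orient="records"),
                }
                report["stage_summaries"] = [s.__dict__ for s in summaries]

    pairs = None
    if use_fixture_pairs:
        pairs = load_fixture_pairs("pooled")
    elif pairs_csv is not None:
        pairs = read_pairs_csv(pairs_csv)
    if pairs is not None:
        log.info("stage=response n_pairs=%d hash=%s", len(pairs), chash)
        cohort = summarize_cohort(pairs)
        report["response"] = cohort.as_dict()
        render_response_heatmap(
            pairs,
            png_path=out / "response_heatmap.png",
            legend_csv_path=out / "response_heatmap_legend.csv",
        )

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def save_slide_bundle(slide: SyntheticSlide, image_path, masks_path=None, spec_json_path=None):
    """Write a synthetic slide as TIFF/PNG plus optional mask archive and
    spec sidecar."""
    image = SlideImage(
        pixels=slide.image, um_per_px=slide.spec.um_per_px, slide_id=slide.slide_id
    )
    write_image(image_path, image)
    if masks_path is not None:
        np.savez_compressed(
            masks_path, tissue_mask=slide.tissue_mask, collagen_mask=slide.collagen_mask
        )
    if spec_json_path is not None:
        Path(spec_json_path).write_text(
            json.dumps(dataclasses.asdict(slide.spec), indent=2, sort_keys=True)
        )
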