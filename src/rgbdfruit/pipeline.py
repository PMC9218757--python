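"""End-to-end detection: the two independent branches and their fusion."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .center_locator import CenterSet, locate_fruit_centers
from .dpc import DpcState, SelectionParams, cluster_blocks
from .fruit_fitter import (MatchedCenter, fit_detections,
                           match_centers_to_regions)
from .rgbd_io import DepthImage, FruitDetection, PipelineConfig, RgbImage
from .superpixels import (BlockSet, SlicParams, block_features, rgb_to_lab,
                          slic_segment)


@dataclass
class PipelineResult:
    detections: list
    centers: CenterSet
    blocks: BlockSet
    dpc: DpcState
    matched: list


def segment_fruit_clusters(rgb: RgbImage, config: PipelineConfig
                           ) -> tuple[BlockSet, DpcState]:
    """Color branch: Lab conversion, SLIC blocks, feature extraction and
    density-peak clustering with coverage pruning."""
    lab = rgb_to_lab(rgb)
    params = SlicParams(k=config.slic_k, m=config.slic_m,
                        max_iter=config.slic_max_iter)
    blocks = slic_segment(lab, params, seed=config.seed)
    blocks = block_features(blocks.labels, rgb)
    selection = SelectionParams(
        n_density_top=config.n_density_top,
        n_delta_top=config.n_delta_top,
        n_keep_clusters=config.n_keep_clusters,
    )
    state = cluster_blocks(blocks.block_features, blocks.block_sizes,
                           sigma=config.kde_sigma, params=selection)
    return blocks, state


def detect_fruits(rgb: RgbImage, depth: DepthImage,
                  config: PipelineConfig | None = None,
                  image: str = "") -> PipelineResult:
    """Run both branches and fuse them into fitted circles.

    The depth branch locates candidate centers from the vorticity of the
    conditioned, 90-degree-rotated depth gradient field; the color branch
    segments the frame into clusters of superpixel blocks.  A center's
    cluster component becomes its fruit region and a circle is fitted by
    the max / min-of-maxima radius rule.
    """
    config = config or PipelineConfig()
    if rgb.shape != depth.shape:
        raise ValueError("RGB and depth grids must be aligned")
    centers = locate_fruit_centers(depth, config)
    blocks, state = segment_fruit_clusters(rgb, config)
    matched = match_centers_to_regions(
        centers, state.labels, blocks,
        min_region_px=config.min_region_px,
        max_region_fraction=config.max_region_fraction)
    detections = fit_detections(matched, config, image=image)
    return PipelineResult(detections=detections, centers=centers,
                          blocks=blocks, dpc=state, matched=matched)
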