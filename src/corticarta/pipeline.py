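"""End-to-end convenience chains over the library modules.

These functions wire the individual steps — synthetic cortex, profiling,
smoothing, decimation, affinity, embedding — into the standard analysis
chain, so that examples, tests and reproduction scripts share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthetic
from .manifold import (
    Embedding,
    PatchAssignment,
    build_affinity,
    decimate_and_patch,
    diffusion_embed,
    patch_profiles,
    profile_flatness,
)
from .mesh import CorticalSheet
from .profiles import ProfileMatrix, smooth_profiles

__all__ = ["AxisResult", "cytoarchitectural_axis"]


@dataclass
class AxisResult:
    """Everything the downstream statistics need from the microstructure arm."""

    sheet: CorticalSheet
    peakedness: np.ndarray
    profiles: ProfileMatrix
    patches: PatchAssignment
    embedding: Embedding

    @property
    def e1(self) -> np.ndarray:
        return self.embedding.e1

    def patch_sphere_coordinates(self) -> np.ndarray:
        return self.sheet.sphere_coordinates[self.patches.retained]

    def patch_hemisphere(self) -> np.ndarray:
        return self.sheet.hemisphere[self.patches.retained]

    def patch_peakedness(self) -> np.ndarray:
        return self.peakedness[self.patches.retained]


def cytoarchitectural_axis(
    n_vertices: int = 2562,
    decimation_factor: int = 12,
    noise_sd: float = 0.1,
    alpha: float = 0.5,
    seed: int = 0,
    smooth: bool = True,
    hemisphere: str = "L",
) -> AxisResult:
    """Full microstructure arm: sheet -> profiles -> affinity -> E1.

    Generates a folded sheet, a bimodal peakedness field and noisy
    staining-intensity profiles; smooths them (three depth iterations,
    two-vertex FWHM surface kernel) unless ``smooth`` is off; decimates the
    chosen hemisphere, builds the partial-correlation affinity and embeds it
    with the given density parameter.  E1's sign is anchored to patch
    profile flatness.
    """
    rng = np.random.SeedSequence(seed).generate_state(3)
    sheet = synthetic.generate_sheet(n_vertices=n_vertices, seed=int(rng[0] % 2**31))
    peak = synthetic.peakedness_field(sheet, seed=int(rng[1] % 2**31))
    profiles, _ = synthetic.generate_profiles(
        sheet, peak, noise_sd=noise_sd, seed=int(rng[2] % 2**31)
    )
    if smooth:
        profiles = smooth_profiles(profiles, sheet)
    mask = sheet.hemisphere == hemisphere
    patches = decimate_and_patch(sheet, mask, factor=decimation_factor)
    affinity = build_affinity(profiles, patches)
    flatness = profile_flatness(patch_profiles(profiles, patches))
    embedding = diffusion_embed(affinity, alpha=alpha, sign_anchor=flatness)
    return AxisResult(
        sheet=sheet,
        peakedness=peak,
        profiles=profiles,
        patches=patches,
        embedding=embedding,
    )
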