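"""Self-contained synthetic multi-section datasets.

Each spot belongs to one of ``n_programs`` latent expression programs. A
program fixes both a gene-expression signature (log-scale mean per gene) and
a distinctive patch appearance (base color + checkerboard frequency), so
patch pixels deterministically encode the program and image-based prediction
is possible in principle. Sections differ by a per-(section, gene) additive
shift on the log scale (slice batch effect) and by a global background tint,
so whole-slice images separate sections while individual patches barely do.

Spots are laid out on a square grid; programs are assigned in rectangular
blocks such that every program forms several disjoint islands — spatially
distant spots of the same program exist by construction, which is exactly
the regime the semantic feature graph is meant to capture.

Counts are sampled per ``noise_model``:

* ``"nb"`` — negative binomial with mean ``exp(signature + shift)`` and
  variance ``mu + dispersion * mu^2``;
* ``"gaussian-on-log"`` — lognormal noise with sd ``dispersion`` on the log
  mean, rounded to integers;
* ``"none"`` — deterministic ``round(mu)`` (noise-free limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .foundation_branch import register_backbone
from .st_data import Section, STDataset

__all__ = ["SyntheticSpec", "generate_dataset", "ToyHistogramBackbone", "toy_backbone"]

# distinct, saturated base colors per program (RGB)
_PROGRAM_COLORS = np.array(
    [
        [200, 80, 80],
        [80, 170, 110],
        [90, 100, 200],
        [200, 180, 70],
        [160, 80, 180],
        [80, 190, 190],
    ],
    dtype=float,
)
_CHECKER_PERIOD = [2, 4, 8, 3, 5, 6]  # pixels; per-program texture frequency


@dataclass
class SyntheticSpec:
    """Default scenario: 4 sections x 64 spots x 30 genes x 3 programs,
    16 px patches, negative-binomial counts, moderate slice batch effect."""

    n_sections: int = 4
    spots_per_section: int = 64
    n_genes: int = 30
    n_programs: int = 3
    image_size: int = 160  # > grid extent so the tinted background shows
    patch_size: int = 16
    slice_effect_sd: float = 0.5
    noise_model: str = "nb"
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_programs > self.spots_per_section:
            raise ValueError("more programs than spots")
        if self.n_programs > len(_PROGRAM_COLORS):
            raise ValueError(f"at most {len(_PROGRAM_COLORS)} programs supported")
        if self.noise_model not in {"nb", "gaussian-on-log", "none"}:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        side = int(round(np.sqrt(self.spots_per_section)))
        if side * side != self.spots_per_section:
            raise ValueError("spots_per_section must be a perfect square (grid layout)")
        if self.image_size < side * self.patch_size:
            raise ValueError("image too small for the spot grid")


def _program_layout(side: int, n_programs: int) -> np.ndarray:
    """Grid of program ids with contiguous blocks AND disjoint same-program islands."""
    rows, cols = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    block = rows // 2 + cols // max(2, side // 2)
    return ((block) % n_programs).astype(int)


def _patch_texture(rng: np.random.Generator, program: int, section_tint: np.ndarray,
                   tint_strength: float, ps: int) -> np.ndarray:
    base = _PROGRAM_COLORS[program]
    period = _CHECKER_PERIOD[program]
    yy, xx = np.meshgrid(np.arange(ps), np.arange(ps), indexing="ij")
    checker = (((yy // period) + (xx // period)) % 2).astype(float)  # 0/1
    img = base[None, None, :] * (0.75 + 0.5 * checker[:, :, None])
    img = img + tint_strength * section_tint[None, None, :]
    img = img + rng.normal(0, 8.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticSpec) -> tuple[STDataset, pd.DataFrame]:
    """Returns (dataset, labels) where labels has columns
    section_id, spot_id, program. Annotations on each section's spot table
    carry the same program labels. Bitwise reproducible for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    side = int(round(np.sqrt(spec.spots_per_section)))
    ps = spec.patch_size
    gene_ids = [f"gene_{g:03d}" for g in range(spec.n_genes)]

    # log-scale signatures: shared per-gene baseline + program effect
    base = rng.normal(3.0, 0.4, size=spec.n_genes)
    effect = rng.normal(0.0, 1.2, size=(spec.n_programs, spec.n_genes))
    signatures = base[None, :] + effect  # (P, G)

    layout = _program_layout(side, spec.n_programs)
    cell = spec.image_size // side  # grid cell in pixels; patch centered inside

    sections, label_rows = [], []
    for s_idx in range(spec.n_sections):
        sid = f"S{s_idx}"
        shift = (
            rng.normal(0.0, spec.slice_effect_sd, size=spec.n_genes)
            if spec.slice_effect_sd > 0
            else np.zeros(spec.n_genes)
        )
        section_tint = rng.uniform(-1.0, 1.0, size=3) * 60.0
        # background carries a strong section-specific tint
        bg = np.clip(180.0 + section_tint, 0, 255)
        image = np.tile(bg.astype(np.uint8), (spec.image_size, spec.image_size, 1))
        image = image + rng.integers(-5, 6, size=image.shape)
        image = np.clip(image, 0, 255).astype(np.uint8)

        spot_rows, counts = [], []
        # patches see only a faint section tint (scaled by the batch-effect size)
        patch_tint = 8.0 * spec.slice_effect_sd
        for r in range(side):
            for c in range(side):
                program = int(layout[r, c])
                px = c * cell + cell // 2
                py = r * cell + cell // 2
                patch = _patch_texture(rng, program, section_tint / 60.0, patch_tint, ps)
                half = ps // 2
                image[py - half : py - half + ps, px - half : px - half + ps] = patch

                mu = np.exp(signatures[program] + shift)
                if spec.noise_model == "nb":
                    d = spec.dispersion
                    if d > 0:
                        n_param = 1.0 / d
                        p_param = n_param / (n_param + mu)
                        cnt = rng.negative_binomial(n_param, p_param)
                    else:
                        cnt = rng.poisson(mu)
                elif spec.noise_model == "gaussian-on-log":
                    cnt = np.round(np.exp(np.log(mu) + rng.normal(0, spec.dispersion, mu.shape)))
                else:
                    cnt = np.round(mu)
                counts.append(cnt.astype(np.int64))

                spot_id = f"{sid}_spot_{r}_{c}"
                spot_rows.append(
                    {"spot_id": spot_id, "px": px, "py": py, "ax": c, "ay": r,
                     "annotation": f"program_{program}"}
                )
                label_rows.append({"section_id": sid, "spot_id": spot_id, "program": program})

        sections.append(
            Section(
                section_id=sid,
                patient_id=f"P{s_idx}",
                image=image,
                spots=pd.DataFrame(spot_rows),
                counts=np.stack(counts),
                gene_ids=gene_ids,
            )
        )

    dataset = STDataset(sections=sections, gene_vocabulary=list(gene_ids))
    return dataset, pd.DataFrame(label_rows)


class ToyHistogramBackbone:
    """Weight-free image encoder: per-channel mean and variance plus an 8-bin
    intensity histogram (14 values). Deterministic, any input size — a drop-in
    stand-in for a pretrained pathology encoder in tests and simulations."""

    name = "toy-histogram"
    n_features = 14

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=float)
        if x.ndim != 3 or x.shape[2] != 3:
            raise ValueError("expected H x W x 3 raster")
        if x.max() > 1.0:
            x = x / 255.0
        means = x.mean(axis=(0, 1))
        variances = x.var(axis=(0, 1))
        intensity = x.mean(axis=2)
        hist, _ = np.histogram(intensity, bins=8, range=(0.0, 1.0))
        hist = hist / intensity.size
        return np.concatenate([means, variances, hist])


def toy_backbone() -> ToyHistogramBackbone:
    return ToyHistogramBackbone()


register_backbone("toy-histogram", toy_backbone)
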