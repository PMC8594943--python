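"""Shared fixtures.

The full-size synthetic atlas libraries are expensive (9,000 nuclei x 2,000
genes each), so they are generated once per session and shared between the
module tests and the acceptance suite. Seeds are fixed so every run sees
identical data.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pytest

import iriskit as ik
from iriskit import synthetic as syn


@pytest.fixture(scope="session")
def atlas_cfg():
    return syn.default_atlas_config()


@pytest.fixture(scope="session")
def lib_untreated_1(atlas_cfg):
    return syn.generate_counts(atlas_cfg, "untreated", replicate=1, seed=1)


@pytest.fixture(scope="session")
def lib_untreated_2(atlas_cfg):
    return syn.generate_counts(atlas_cfg, "untreated", replicate=2, seed=2)


@pytest.fixture(scope="session")
def lib_dilated(atlas_cfg):
    return syn.generate_counts(atlas_cfg, "dilated", replicate=1, seed=11)


@pytest.fixture(scope="session")
def lib_constricted(atlas_cfg):
    return syn.generate_counts(atlas_cfg, "constricted", replicate=1, seed=21)


@pytest.fixture(scope="session")
def norm_untreated_1(lib_untreated_1):
    """QC-filtered, normalized single untreated library."""
    adata, _ = lib_untreated_1
    filtered, _report = ik.qc_filter(adata)
    return ik.normalize(filtered)


@pytest.fixture(scope="session")
def norm_three_conditions(lib_untreated_1, lib_dilated, lib_constricted):
    """QC-filtered, normalized merge of one library per condition."""
    merged = ad.concat(
        [lib_untreated_1[0], lib_dilated[0], lib_constricted[0]], merge="same"
    )
    filtered, _report = ik.qc_filter(merged)
    return ik.normalize(filtered)


@pytest.fixture(scope="session")
def profile_three_conditions(norm_three_conditions):
    return ik.pseudobulk(norm_three_conditions)


def small_config(seed: int = 0, **kwargs) -> syn.AtlasConfig:
    """A fast, fully consistent atlas config for unit tests."""
    defaults = dict(n_genes=1200, n_nuclei_per_library=400, seed=seed)
    defaults.update(kwargs)
    return syn.default_atlas_config(**defaults)


def null_config(n_genes: int = 200, n_nuclei: int = 40,
                seed: int = 0) -> syn.AtlasConfig:
    """Two interchangeable populations, no planted effects, no replicate
    jitter: the exact null for differential-expression error control."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    return syn.AtlasConfig(
        genes=genes,
        cell_type_catalogue=[("a", 0.5), ("b", 0.5)],
        marker_programs={},
        dilation_program={},
        mito_gene_ids=[],
        base_weights=rng.lognormal(0.0, 1.5, n_genes),
        n_nuclei_per_library=n_nuclei,
        target_mean_detected=1000.0,
        replicate_jitter_sd=0.0,
        qc_low_frac=0.0,
        qc_high_frac=0.0,
        qc_mito_frac=0.0,
        seed=seed,
    )
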