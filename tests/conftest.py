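"""Shared fixtures: seeded volumes, phantom cohorts and their feature tables.

The cohort-level fixtures are session-scoped because generating and
processing ~100 phantoms is the dominant cost of the suite; every test that
needs cohort features shares one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ironmap.feature_selection import FeatureTable
from ironmap.hybrid_contrast import build_system, fuse, solve_weights
from ironmap.io_preproc import LabelMask, RegistrationConfig, Volume
from ironmap.radiomics import ExtractionConfig, extract_all
from ironmap.segmentation import DeformationProvider, misalign_mask, propagate_labels
from ironmap.synthetic_data import (
    LEGEND,
    PhantomSpec,
    generate_cohort,
    generate_template,
)

#: deliberate mask placement error (voxels) emulating an iron-blind
#: atlas segmentation: a 3-voxel medial drift on each hemisphere plus a
#: 2-voxel anterior drift, off the posterolateral iron deposits
MISALIGN_OFFSET = (3, 2, 0)


def make_volume(rng: np.random.Generator, shape=(16, 16, 16), spacing=(1, 1, 1)):
    affine = np.diag([*spacing, 1.0])
    return Volume(rng.normal(100.0, 15.0, size=shape), affine, "T1w")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def template_pair():
    return generate_template()


@pytest.fixture(scope="session")
def msap_pd_cohort():
    """34 MSA-P + 56 PD phantoms at the generator defaults."""
    return generate_cohort({"MSA-P": 34, "PD": 56}, PhantomSpec(), master_seed=7)


def _feature_row(swi, mask, config):
    return extract_all(swi, mask, "putamen", config).texture_safe().to_series()


@pytest.fixture(scope="session")
def cohort_tables(msap_pd_cohort, template_pair):
    """Feature tables of the MSA-P/PD cohort under three masks:

    * ``truth`` — the generator's exact masks;
    * ``hc`` — masks propagated from the template through registration of
      the hybrid-contrast image;
    * ``misaligned`` — the HC masks displaced by a fixed offset, the
      T1w-only-segmentation surrogate.

    Also returns the per-subject putamen Dice of the HC masks.
    """
    template, template_mask = template_pair
    reg = RegistrationConfig.fast()
    config = ExtractionConfig()
    rows = {"truth": {}, "hc": {}, "misaligned": {}}
    labels = {}
    dice = []
    for i, s in enumerate(msap_pd_cohort):
        sid = f"sub-{i:03d}"
        labels[sid] = s.class_name
        weights = solve_weights(build_system(s.t1w, s.swi, s.truth, template, template_mask))
        hc = fuse(s.t1w, s.swi, weights)
        provider = DeformationProvider.from_registration(hc, template, reg)
        hc_mask = propagate_labels(hc, template, template_mask, provider)
        inter = np.logical_and(hc_mask.labels == 1, s.truth.labels == 1).sum()
        dice.append(2.0 * inter / ((hc_mask.labels == 1).sum() + (s.truth.labels == 1).sum()))
        rows["truth"][sid] = _feature_row(s.swi, s.truth, config)
        rows["hc"][sid] = _feature_row(s.swi, hc_mask, config)
        rows["misaligned"][sid] = _feature_row(
            s.swi, misalign_mask(hc_mask, MISALIGN_OFFSET), config
        )
    label_series = pd.Series(labels, name="class")
    tables = {
        key: FeatureTable(pd.DataFrame(val).T.loc[label_series.index], label_series)
        for key, val in rows.items()
    }
    tables["putamen_dice"] = np.asarray(dice)
    return tables


@pytest.fixture(scope="session")
def null_table():
    """Zero-effect-size cohort: classes differ only through noise draws."""
    spec = PhantomSpec(depth=0.0)
    subjects = generate_cohort({"MSA-P": 20, "PD": 20}, spec, master_seed=11)
    config = ExtractionConfig()
    rows = {}
    labels = {}
    for i, s in enumerate(subjects):
        sid = f"null-{i:03d}"
        labels[sid] = s.class_name
        rows[sid] = _feature_row(s.swi, s.truth, config)
    label_series = pd.Series(labels, name="class")
    return FeatureTable(pd.DataFrame(rows).T.loc[label_series.index], label_series)


@pytest.fixture
def simple_mask():
    """A 12x12x12 grid with a 4-cube putamen, 2-cube pallidum, WM elsewhere."""
    labels = np.zeros((12, 12, 12), dtype=np.int32)
    labels[:, :, :] = 3
    labels[2:6, 2:6, 2:6] = 1
    labels[8:10, 8:10, 8:10] = 2
    grid = Volume(np.zeros((12, 12, 12)), np.eye(4), "T1w")
    return LabelMask(labels, grid, LEGEND)
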