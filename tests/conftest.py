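import numpy as np
import pytest

from histoseg.phantom import (corrupt_coarse_segmentation, make_phantom_atlas,
                              phantom_bias_grouping, phantom_protocol,
                              phantom_recipe, sample_image)


@pytest.fixture(scope="session")
def small_phantom():
    """32-cube phantom with 8 ROIs in 4 classes, shared across unit tests."""
    atlas, grouping = make_phantom_atlas(seed=7, grid_shape=(32, 32, 32),
                                         n_rois=8, n_classes=4)
    return atlas, grouping


@pytest.fixture(scope="session")
def phantom_study(small_phantom):
    """Sampled image + coarse segmentation + configs for the small phantom."""
    atlas, grouping = small_phantom
    image, truth = sample_image(atlas, grouping, max_displacement=2.0, seed=7)
    roi_to_protocol, names = phantom_protocol(atlas)
    coarse = corrupt_coarse_segmentation(truth.true_labels, roi_to_protocol, names,
                                         error_rate=0.05, seed=11,
                                         affine=atlas.affine)
    return {
        "atlas": atlas, "grouping": grouping, "image": image, "truth": truth,
        "coarse": coarse, "roi_to_protocol": roi_to_protocol, "names": names,
        "recipe_rules": phantom_recipe(atlas, grouping, names),
        "bias_classes": phantom_bias_grouping(grouping, roi_to_protocol, names),
    }


@pytest.fixture(scope="session")
def default_phantom_study():
    """Default-size phantom (64-cube, 24 ROIs, 6 classes): the study conditions."""
    atlas, grouping = make_phantom_atlas(seed=1)
    image, truth = sample_image(atlas, grouping, seed=1)
    roi_to_protocol, names = phantom_protocol(atlas)
    coarse = corrupt_coarse_segmentation(truth.true_labels, roi_to_protocol, names,
                                         error_rate=0.05, seed=5,
                                         affine=atlas.affine)
    return {
        "atlas": atlas, "grouping": grouping, "image": image, "truth": truth,
        "coarse": coarse, "roi_to_protocol": roi_to_protocol, "names": names,
        "recipe_rules": phantom_recipe(atlas, grouping, names),
        "bias_classes": phantom_bias_grouping(grouping, roi_to_protocol, names),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
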