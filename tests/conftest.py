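import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import ishquant as iq


@pytest.fixture(scope="session")
def default_field():
    """One default simulated field with its ground truth (shared, read-only)."""
    return iq.simulate_field(iq.SimConfig(), seed=42)


@pytest.fixture(scope="session")
def quantified_field(default_field):
    """Full single-field quantification products for the default field."""
    stack, gt = default_field
    nuclei = iq.segment_nuclei(stack.channels[stack.nucleus_channel])
    masks = iq.expand_masks(nuclei)
    assignments = {}
    for ch in stack.transcript_channel_names:
        spots = iq.detect_spots(stack.channels[ch], channel=ch)
        assignments[ch] = (spots, iq.assign_spots_to_cells(spots, masks))
    table = iq.quantify_cells(masks, assignments, stack.pixel_size_um, nuclei=nuclei)
    return {"stack": stack, "gt": gt, "nuclei": nuclei, "masks": masks,
            "assignments": assignments, "table": table}


def high_res_typing_config(n_cells: int = 30) -> iq.SimConfig:
    """Marker-typing validation regime: resolvable puncta at 0.25 um/px,
    strong own markers (NB mean 15, dispersion 10), trace off markers."""
    count_model = {
        "glutamatergic": {
            "Gprc5b": iq.CountModel(distribution="negative_binomial", mean=3, dispersion=2),
            "Slc17a7": iq.CountModel(distribution="negative_binomial", mean=15, dispersion=10),
            "Gad1": iq.CountModel(distribution="poisson", mean=0.1),
        },
        "GABAergic": {
            "Gprc5b": iq.CountModel(distribution="negative_binomial", mean=8, dispersion=2),
            "Slc17a7": iq.CountModel(distribution="poisson", mean=0.1),
            "Gad1": iq.CountModel(distribution="negative_binomial", mean=15, dispersion=10),
        },
    }
    return iq.SimConfig(field_size_px=(448, 448), pixel_size_um=0.25, n_cells=n_cells,
                        min_nucleus_separation_px=32.0, psf_sigma_px=1.2,
                        count_model=count_model)


def quantify_one(stack, detection=None):
    """Segment + expand + detect + score one stack; returns (table, masks, nuclei)."""
    nuclei = iq.segment_nuclei(stack.channels[stack.nucleus_channel])
    masks = iq.expand_masks(nuclei)
    assignments = {}
    for ch in stack.transcript_channel_names:
        spots = iq.detect_spots(stack.channels[ch], detection, channel=ch)
        assignments[ch] = (spots, iq.assign_spots_to_cells(spots, masks))
    table = iq.quantify_cells(masks, assignments, stack.pixel_size_um, nuclei=nuclei)
    return table, masks, nuclei
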