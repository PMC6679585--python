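import numpy as np
import pytest

from memtopo import optics_sim, quantify


@pytest.fixture(scope="session")
def topology_sim():
    """Noise-free and noisy camera images of the reference cortex scene
    (single bilayer + furrow double membrane + tangent 100-nm tube)."""
    scene, ann = optics_sim.filopodium_furrow_scene()
    cfg = optics_sim.OpticsConfig(seed=7)
    clean = optics_sim.simulate_membrane_image(scene, cfg, noise=False)
    noisy = optics_sim.add_noise(clean, cfg)
    return {"scene": scene, "ann": ann, "cfg": cfg, "clean": clean,
            "noisy": noisy}


def topology_ratios(sim, ann):
    """Filo/PM and Furrow/PM medians of the normalized top-3 metric."""
    img = sim.channel(0)
    bg = float(np.median(img[:3]))  # rows far from the membrane
    path = quantify.MembranePath(np.asarray(ann["path_px"]))
    off = ann["path_offset_px"]
    crossings = [quantify.Crossing(label=c["label"],
                                   center_px=c["center_px"] - off,
                                   halfwidth_px=ann["halfwidth_px"])
                 for c in ann["crossings"]]
    recs = quantify.enrichment_table(img, path, crossings,
                                     cytoplasm_background=bg,
                                     pixel_size_um=sim.pixel_size_um)
    med = lambda lab: float(np.median([r.normalized for r in recs
                                       if r.label == lab]))
    return med("Filo"), med("Furrow")
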