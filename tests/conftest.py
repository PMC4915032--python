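import numpy as np
import pytest

from spinemetry import morphometry as mo
from spinemetry import pipeline as pipe
from spinemetry import synthetic as syn


def make_single_spine(neck_length=0.40, neck_width=0.16, head_width=0.44,
                      angle_deg=90.0, sagitta=0.0, dendrite_radius=0.35,
                      dendrite_length=1.8):
    """One hand-built spine on a short dendrite segment, base at the
    segment midpoint."""
    ang = np.radians(angle_deg)
    direction = np.array([np.cos(ang), np.sin(ang), 0.0])
    attach = np.array([dendrite_length / 2, 0.0, 0.0]) + direction * dendrite_radius
    geom = syn._build_geometry(attach, direction, neck_length, neck_width,
                               head_width, sagitta)
    rec = syn.SpineRecord(spine_id="s0", geometry=geom,
                          seed_point_um=attach[:2].copy(),
                          head_hint_um=geom.head_center[:2].copy())
    dend = np.array([[0.0, 0.0, 0.0], [dendrite_length, 0.0, 0.0]])
    return syn.GroundTruthAnnotation(spines=[rec], dendrite_path=dend,
                                     dendrite_length=dendrite_length,
                                     dendrite_radius=dendrite_radius)


def render_and_project(annotation, imaging=None, seed=0):
    imaging = imaging or syn.ImagingConfig(noise_model=None)
    stack = syn.render_stack(annotation, imaging, seed)
    image, px = mo.project_stack(stack)
    table = pipe.annotation_to_pixel_table(annotation, imaging)
    return stack, image, px, table


@pytest.fixture(scope="session")
def noiseless_imaging():
    return syn.ImagingConfig(noise_model=None)


@pytest.fixture(scope="session")
def straight_spine():
    """Rendered noiseless straight spine (0.40/0.16/0.44 um) + metadata."""
    ann = make_single_spine()
    stack, image, px, table = render_and_project(ann)
    return {"annotation": ann, "stack": stack, "image": image,
            "pixel_size": px, "table": table}
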