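import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import septalge as s

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def circle(cx, cy, r, n=128):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


def blank_stack(n_slices=1, size=80, pixel_spacing=1.0, fill=0.0):
    return s.ImageStack(
        voxels=np.full((n_slices, size, size), fill, dtype=float),
        pixel_spacing=pixel_spacing,
    )


@pytest.fixture(scope="session")
def striae_phantom():
    """One phantom with a single mid-wall septal striae lesion."""
    spec = s.PhantomSpec(lesion_list=(s.LesionSpec(),), noise_seed=7)
    stack, contours, truth = s.generate_phantom(spec)
    return spec, stack, contours, truth


@pytest.fixture(scope="session")
def analyzed_phantom(striae_phantom):
    spec, stack, contours, truth = striae_phantom
    masks, stats, results = s.analyze_stack(stack, contours)
    return spec, truth, masks, stats, results


@pytest.fixture(scope="session")
def paper_count_cohort():
    """118-patient event-indicator table matching the published event tally:
    7 cardiac deaths (one also receiving appropriate ICD therapy, one sudden),
    14 appropriate ICD therapies, 5 non-cardiac deaths."""
    import pandas as pd

    n = 118
    cardiac_death = [0] * n
    icd = [0] * n
    scd = [0] * n
    nc = [0] * n
    for i in range(13):  # ICD therapy only
        icd[i] = 1
    icd[13] = 1  # both ICD therapy and cardiac death
    cardiac_death[13] = 1
    for i in range(14, 19):  # cardiac death only
        cardiac_death[i] = 1
    cardiac_death[19] = 1  # sudden cardiac death, no ICD
    scd[19] = 1
    for i in range(20, 25):
        nc[i] = 1
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "followup_years": np.full(n, 2.0),
            "cardiac_death": cardiac_death,
            "appropriate_icd": icd,
            "scd": scd,
            "noncardiac_death": nc,
        }
    )
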