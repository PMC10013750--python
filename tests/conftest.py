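import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from necroseq import simulate as sim

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_tx():
    """20 ortholog pairs, 300 bp, 10% divergence."""
    return sim.generate_transcriptomes(n_genes=20, length=300, divergence=0.10, seed=11)


@pytest.fixture(scope="session")
def marker_genes():
    return [f"g{i:04d}" for i in range(2000)]


@pytest.fixture()
def square_scene():
    """2000 um square tumor with a 600 um central necrotic zone."""
    tumor = [(0, 0), (2000, 0), (2000, 2000), (0, 2000)]
    necrosis = [[(700, 700), (1300, 700), (1300, 1300), (700, 1300)]]
    return tumor, necrosis


def star_polygon(rng: np.random.Generator, n_vertices: int = 8,
                 r_lo: float = 50.0, r_hi: float = 200.0,
                 center=(0.0, 0.0)) -> list[tuple[float, float]]:
    """Random simple (star-shaped) polygon around a center."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(r_lo, r_hi, n_vertices)
    cx, cy = center
    return [(cx + r * np.cos(a), cy + r * np.sin(a)) for r, a in zip(radii, angles)]


def paired_plasma(n_proteins=30, n_increased=17, n_subjects=3, shift=2.0):
    """Deterministic paired early/late plasma fixture: exactly
    ``n_increased`` proteins rise by ``shift`` log2 units in every subject."""
    from necroseq.containers import PlasmaTable

    proteins = [f"P{i:03d}" for i in range(n_proteins)]
    samples, meta = [], []
    for s in range(n_subjects):
        for tp in ("early", "late"):
            samples.append(f"S{s}_{tp}")
            meta.append((f"S{s}", tp))
    data = np.full((n_proteins, len(samples)), 20.0)
    for j, (_, tp) in enumerate(meta):
        if tp == "late":
            data[:n_increased, j] += shift
    abundance = pd.DataFrame(data, index=proteins, columns=samples)
    sample_meta = pd.DataFrame(meta, columns=["subject", "timepoint"], index=samples)
    return PlasmaTable(abundance, sample_meta), proteins[:n_increased]


def ctc_cohort(n=40, n_ctc=29, n_cluster=5):
    """Cohort fixture: ``n_ctc`` subjects with >=1 single CTC (the first
    ``n_cluster`` of them also with a cluster), the rest with none."""
    rows = []
    for i in range(n):
        s = f"S{i:03d}"
        single = 3 if i < n_ctc else 0
        cluster = 1 if i < n_cluster else 0
        rows.append((s, 0, 0, 0))
        rows.append((s, 1, single, cluster))
    return pd.DataFrame(rows, columns=["subject", "timepoint", "single_ctc", "ctc_cluster"])
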