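import numpy as np
import pytest

from sock.synthetic import PhantomSpec, generate_phantom, write_phantom_melodic_dir


@pytest.fixture(scope="session")
def phantom():
    """Default 15-component phantom (3 per class), fixed seed."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def melodic_dir(tmp_path_factory, phantom):
    """The same phantom written out in the MELODIC directory layout."""
    path = tmp_path_factory.mktemp("phantom_melodic")
    write_phantom_melodic_dir(phantom, str(path))
    return path


def direct_dft3(volume: np.ndarray) -> np.ndarray:
    """O(n^2) reference 3D DFT, loop over output frequencies."""
    volume = np.asarray(volume, dtype=complex)
    nx, ny, nz = volume.shape
    out = np.empty_like(volume)
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]
    for kx in range(nx):
        for ky in range(ny):
            for kz in range(nz):
                phase = np.exp(-2j * np.pi * (kx * x / nx + ky * y / ny + kz * z / nz))
                out[kx, ky, kz] = (volume * phase).sum()
    return out


def _offsets(connectivity):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def flood_fill_labels(active: np.ndarray, connectivity: int) -> np.ndarray:
    """Reference connected-component labeling via explicit flood fill."""
    active = np.asarray(active).astype(bool)
    labels = np.zeros(active.shape, dtype=int)
    offs = _offsets(connectivity)
    current = 0
    for start in zip(*np.nonzero(active)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            vx = stack.pop()
            for off in offs:
                nb = tuple(v + o for v, o in zip(vx, off))
                if any(c < 0 or c >= s for c, s in zip(nb, active.shape)):
                    continue
                if active[nb] and not labels[nb]:
                    labels[nb] = current
                    stack.append(nb)
    return labels


def best_bipartition_sse(values: np.ndarray):
    """Reference: exhaustive minimum within-cluster-SSE 2-partition.

    Enumerates every nonempty bipartition (no contiguity assumption) and
    returns (best SSE, boolean membership of the higher-mean cluster)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    codes = np.arange(1, 2**n - 1)
    member = ((codes[:, None] >> np.arange(n)) & 1).astype(bool)  # (codes, n)

    def within_sse(m):
        sizes = m.sum(axis=1)
        sums = m @ values
        sums2 = m @ values**2
        return sums2 - sums**2 / sizes

    sse = within_sse(member) + within_sse(~member)
    best = int(np.argmin(sse))
    m = member[best]
    if values[m].mean() < values[~m].mean():
        m = ~m
    return float(sse[best]), m
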