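import numpy as np
import pytest

import pmbind as pb


# ---------------------------------------------------------------------------
# independent brute-force morphology oracle
# ---------------------------------------------------------------------------

def erode_oracle(mask: np.ndarray, n: int = 1) -> np.ndarray:
    """Erosion by explicit neighborhood set arithmetic (8-connected, 3x3).

    A pixel survives iff its full 3x3 neighborhood lies inside the mask
    (neighbors outside the image count as background).  Deliberately naive:
    used only to cross-check the package's morphology on small shapes.
    """
    mask = np.asarray(mask, dtype=bool)
    for _ in range(n):
        out = np.zeros_like(mask)
        rows, cols = mask.shape
        for r in range(rows):
            for c in range(cols):
                if not mask[r, c]:
                    continue
                ok = True
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < rows and 0 <= cc < cols and mask[rr, cc]):
                            ok = False
                if ok:
                    out[r, c] = True
        mask = out
    return mask


def flood_fill_components(mask: np.ndarray) -> list:
    """Connected components by explicit BFS flood fill (8-connected)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = np.zeros_like(mask)
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp[r, c] = True
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < rows and 0 <= cc < cols
                                    and mask[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


@pytest.fixture(scope="session")
def noiseless_params():
    """Membrane 200 / cytosol 50 AFU, no noise, no background."""
    return pb.CellRenderParams(
        membrane_intensity=200.0, cytosol_intensity=50.0, background=0.0,
        poisson_noise=False, gaussian_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_cell(noiseless_params):
    return pb.render_cell_image(noiseless_params)
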