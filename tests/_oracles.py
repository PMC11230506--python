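"""Independent brute-force oracles used by the test suite."""

import numpy as np


def grid_search_rmsd(p, q, zoom_levels=9, n=7):
    """Zooming Euler-angle grid search for the minimum superposition RMSD."""
    from scipy.spatial.transform import Rotation

    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)

    def cost(a, b, g):
        r = Rotation.from_euler("zyz", [a, b, g]).as_matrix()
        d = qc - pc @ r.T
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    best_cost = np.inf
    best_angles = np.array([0.0, np.pi / 2, 0.0])
    for a in np.linspace(-np.pi, np.pi, 11):
        for b in np.linspace(0, np.pi, 7):
            for g in np.linspace(-np.pi, np.pi, 11):
                c = cost(a, b, g)
                if c < best_cost:
                    best_cost, best_angles = c, np.array([a, b, g])
    widths = np.array([np.pi, np.pi / 2, np.pi]) / 3.0
    for _ in range(zoom_levels):
        ctr = best_angles.copy()
        for a in np.linspace(ctr[0] - widths[0], ctr[0] + widths[0], n):
            for b in np.linspace(ctr[1] - widths[1], ctr[1] + widths[1], n):
                for g in np.linspace(ctr[2] - widths[2], ctr[2] + widths[2], n):
                    c = cost(a, b, g)
                    if c < best_cost:
                        best_cost, best_angles = c, np.array([a, b, g])
        widths = widths / 3.0
    return best_cost
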