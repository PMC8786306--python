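import numpy as np
import pytest

from cryoclass.ctf import CtfParams, ctf_eval
from cryoclass.grids import fourier_grid, rfft_image
from cryoclass.likelihood import NoiseSpectrum
from cryoclass.simulate import make_classes, simulate_particles
from cryoclass.transform import make_pose_grid


@pytest.fixture(scope="session")
def small_stack():
    """600-particle stack at the standard conditions (shared across tests)."""
    classes = make_classes(3, 32, seed=5)
    stack, truth = simulate_particles(classes, n_particles=600, seed=7)
    return classes, stack, truth


@pytest.fixture()
def toy_problem():
    """Small random references/particles on an 8x8 grid with a 90-degree
    pose grid (where all analytic identities are exact)."""
    rng = np.random.default_rng(1)
    box = 8
    g = fourier_grid(box)
    K, B = 2, 3
    refs = rng.standard_normal((K, box, box))
    imgs = rng.standard_normal((B, box, box))

    def prep(r):
        h = rfft_image(r).astype(np.complex128)
        h[..., ~g.active_half] = 0
        return h

    fy = g.unpack(g.freq_in_inv_angstrom(2.0)[0])
    fx = g.unpack(g.freq_in_inv_angstrom(2.0)[1])
    params = [CtfParams(12000 + 2000 * i, 11000 + 1500 * i, 20.0 * i)
              for i in range(B)]
    ch = np.stack([np.where(g.active_half, ctf_eval(p, fy, fx), 0)
                   for p in params])
    sigma = NoiseSpectrum(0.5 + np.linspace(0, 1, g.n_shells))
    grid = make_pose_grid(90.0, 1, 1, 1.5, box=box)
    return dict(box=box, g=g, refs=refs, imgs=imgs, xh=prep(imgs),
                vh=prep(refs), ch=ch, params=params, sigma=sigma, grid=grid)


def best_alignment_correlation(truth_img, avg, rot_step=5, max_shift=3):
    """Highest Pearson correlation between a recovered average and the
    ground-truth image over grid rotations and integer shifts."""
    from cryoclass.transform import rotate_real
    best = -1.0
    ca = avg - avg.mean()
    na = np.sqrt((ca ** 2).sum())
    for psi in range(0, 360, rot_step):
        r = rotate_real(truth_img, psi)
        for sy in range(-max_shift, max_shift + 1):
            for sx in range(-max_shift, max_shift + 1):
                rr = np.roll(np.roll(r, sy, 0), sx, 1)
                cb = rr - rr.mean()
                best = max(best, float((ca * cb).sum()
                                       / (na * np.sqrt((cb ** 2).sum()))))
    return best


def label_accuracy(pred_classes, true_classes, K):
    """Best class-assignment accuracy over label permutations (Hungarian)."""
    from scipy.optimize import linear_sum_assignment
    C = np.zeros((K, K))
    for p, t in zip(pred_classes, true_classes):
        C[p, t] += 1
    r, c = linear_sum_assignment(-C)
    return C[r, c].sum() / len(true_classes)
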