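"""Full-model ELBO assembly, serialization and modular recomposition."""

import copy
import os

import numpy as np
import pytest

from vcgpdm import SyntheticSpec, TrajectorySet, VCGPDM, compose, load, make_dataset, save
from vcgpdm import dynamics as dyn
from vcgpdm import kernels as kr
from vcgpdm import variational as vgp


@pytest.fixture(scope="module")
def two_part_model(small_data):
    data, _, seed = small_data
    model = VCGPDM(data, latent_dims=2, order=2, n_dyn_ips=4, n_kin_ips=5,
                   seed=seed)
    model.initialize()
    return model


def single_part_model(seed=0, T=30):
    rng = np.random.default_rng(seed)
    Y = np.column_stack([np.sin(np.linspace(0, 6 * np.pi, T) + p)
                         for p in rng.uniform(0, 2 * np.pi, 6)])
    Y += 0.05 * rng.standard_normal(Y.shape)
    data = TrajectorySet([Y], np.zeros(6, dtype=int))
    model = VCGPDM(data, latent_dims=2, order=2, n_dyn_ips=4, n_kin_ips=5,
                   seed=seed)
    model.initialize()
    return model


class TestElbo:
    def test_decomposes_into_kinematics_and_dynamics(self, two_part_model):
        m = two_part_model
        decomp = m.elbo_parts()
        assert m.elbo() == pytest.approx(sum(decomp["kin"]) + decomp["dyn"],
                                         rel=1e-12)
        # kinematics summands equal independently computed collapsed bounds
        for i, part in enumerate(m.parts):
            bel = kr.GaussianBelief(part.latent.mean, part.latent.variance)
            Y = np.vstack(m.data.part_data(i))
            direct = vgp.collapsed_bound(Y, part.kin_kernel, part.kin_inducing,
                                         bel, part.beta, m.jitter)
            assert decomp["kin"][i] == pytest.approx(direct, rel=1e-12)

    def test_single_part_elbo_equals_dedicated_vgpdm_path(self):
        m = single_part_model()
        part = m.parts[0]
        bel = kr.GaussianBelief(part.latent.mean, part.latent.variance)
        Y = np.vstack(m.data.part_data(0))
        kin = vgp.collapsed_bound(Y, part.kin_kernel, part.kin_inducing, bel,
                                  part.beta, m.jitter)
        c = m.couplings[(0, 0)]
        ar = kr.GaussianBelief(m._ar_stack(part.latent.mean),
                               m._ar_stack(part.latent.variance))
        Z = c.inducing.locations
        Kuu = kr.gram(c.kernel, Z) + m.jitter * c.kernel.variance \
            * np.eye(Z.shape[0])
        dyn_val = dyn.vgpdm_dynamics_bound(
            part.latent.mean[m._ar_targets], part.latent.variance[m._ar_targets],
            Kuu, kr.psi1(c.kernel, Z, ar), kr.psi2(c.kernel, Z, ar),
            kr.psi0(c.kernel, ar), c.alpha)
        # replicate the model's accumulation order exactly
        dyn_val += dyn.entropy(part.latent.mean, part.latent.variance)
        for sl in m.seq_slices:
            head = slice(sl.start, sl.start + m.order)
            dyn_val += dyn.initial_state_term(part.latent.mean[head],
                                              part.latent.variance[head])
        assert m.elbo() == kin + dyn_val

    def test_finite_difference_gradients(self, two_part_model):
        m = two_part_model
        keys = m.free_keys(None)
        theta0 = m.pack(keys)
        _, grads = m.elbo_with_grads()
        g = np.concatenate([np.ravel(grads[k]) for k in keys])
        rng = np.random.default_rng(0)
        idx = rng.choice(theta0.size, 20, replace=False)
        for i in idx:
            eps = 1e-5
            tp = theta0.copy()
            tp[i] += eps
            m.unpack(keys, tp)
            fp = m.elbo()
            tm = theta0.copy()
            tm[i] -= eps
            m.unpack(keys, tm)
            fm = m.elbo()
            fd = (fp - fm) / (2 * eps)
            denom = max(abs(fd), abs(g[i]), 1e-6)
            assert abs(fd - g[i]) / denom < 1e-4
        m.unpack(keys, theta0)

    def test_invariant_under_part_relabeling(self, small_data):
        data, _, seed = small_data
        m1 = VCGPDM(data, latent_dims=2, n_dyn_ips=4, n_kin_ips=5, seed=seed)
        m1.initialize()
        # swap the two parts: permute columns and the column map
        perm = np.concatenate([data.part_columns(1), data.part_columns(0)])
        data2 = TrajectorySet([s[:, perm] for s in data.sequences],
                              np.concatenate([np.zeros(len(data.part_columns(1)), int),
                                              np.ones(len(data.part_columns(0)), int)]))
        m2 = VCGPDM(data2, latent_dims=2, n_dyn_ips=4, n_kin_ips=5, seed=seed)
        m2.initialize()
        m2.parts = [copy.deepcopy(m1.parts[1]), copy.deepcopy(m1.parts[0])]
        for i, p in enumerate(m2.parts):
            p.index = i
        m2.couplings = {(1 - i, 1 - j): copy.deepcopy(c)
                        for (i, j), c in m1.couplings.items()}
        assert m2.elbo() == pytest.approx(m1.elbo(), rel=1e-10)

    def test_severed_couplings_recover_independent_parts(self, small_data):
        data, _, seed = small_data
        m = VCGPDM(data, latent_dims=2, n_dyn_ips=4, n_kin_ips=5, seed=seed)
        m.initialize()
        for (i, j), c in m.couplings.items():
            if i != j:
                c.alpha = 1e8
        coupled = m.elbo()
        # independent single-part models with identical parameters
        total = 0.0
        for i in range(2):
            cols = data.part_columns(i)
            d_i = TrajectorySet([s[:, cols] for s in data.sequences],
                                np.zeros(len(cols), dtype=int))
            mi = VCGPDM(d_i, latent_dims=2, n_dyn_ips=4, n_kin_ips=5, seed=seed)
            mi.initialize()
            mi.parts = [copy.deepcopy(m.parts[i])]
            mi.parts[0].index = 0
            mi.couplings = {(0, 0): copy.deepcopy(m.couplings[(i, i)])}
            total += mi.elbo()
        assert coupled == pytest.approx(total, rel=1e-4)

    def test_too_short_sequences_rejected(self):
        data = TrajectorySet([np.zeros((2, 4))], np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError):
            VCGPDM(data, order=2)


class TestSerialization:
    def test_roundtrip_elbo_bit_exact(self, fitted, small_data, tmp_path):
        model, _ = fitted
        data = small_data[0]
        p = tmp_path / "model.npz"
        save(model, p, include_posterior=True)
        loaded = load(p, data=data)
        assert loaded.elbo() == model.elbo()

    def test_compact_archive_size_independent_of_T(self, tmp_path):
        sizes = []
        for T in (100, 300):
            data, _ = make_dataset(SyntheticSpec(T=T, seed=5))
            m = VCGPDM(data, latent_dims=2, n_dyn_ips=4, n_kin_ips=5, seed=0)
            m.initialize()
            m.update_posteriors()
            p = tmp_path / f"m{T}.npz"
            save(m, p)
            sizes.append(os.path.getsize(p))
        assert sizes[0] == sizes[1]

    def test_loaded_components_preserve_parameters(self, fitted, tmp_path):
        model, _ = fitted
        p = tmp_path / "model.npz"
        save(model, p)
        loaded = load(p)
        for i, part in enumerate(model.parts):
            assert np.array_equal(loaded.parts[i].kin_inducing.locations,
                                  part.kin_inducing.locations)
            assert loaded.parts[i].beta == part.beta
        for key, c in model.couplings.items():
            assert loaded.couplings[key].alpha == c.alpha
            assert np.array_equal(loaded.couplings[key].posterior.mean,
                                  c.posterior.mean)

    def test_corrupted_archive_rejected(self, tmp_path):
        p = tmp_path / "bad.npz"
        np.savez(p, junk=np.zeros(3))
        with pytest.raises((ValueError, KeyError)):
            load(p)


class TestCompose:
    def test_identity_recomposition_reproduces_elbo(self, fitted, small_data):
        model, _ = fitted
        data = small_data[0]
        c = compose([copy.deepcopy(p) for p in model.parts],
                    {k: copy.deepcopy(v) for k, v in model.couplings.items()},
                    data, order=model.order, retrain_alphas=False,
                    jitter=model.jitter)
        assert c.elbo() == model.elbo()

    def test_only_alphas_trainable_by_default(self, fitted, small_data):
        model, _ = fitted
        c = compose(model.parts, model.couplings, small_data[0],
                    order=model.order)
        keys = c.free_keys(None)
        assert keys and all(k[0] == "logalpha" for k in keys)

    def test_shared_part_shares_archive_bytes(self, fitted, small_data, tmp_path):
        """Two recombined variants built on the same lower part store
        byte-identical lower-part arrays."""
        model, _ = fitted
        data = small_data[0]
        paths = []
        for variant in range(2):
            parts = [copy.deepcopy(model.parts[0]),
                     copy.deepcopy(model.parts[1])]
            # variant-specific upper body: perturb only part 1's kinematics
            parts[1].kin_kernel.variance *= (1.0 + 0.5 * variant)
            c = compose(parts,
                        {k: copy.deepcopy(v) for k, v in model.couplings.items()},
                        data, order=model.order, jitter=model.jitter)
            c.update_posteriors()
            p = tmp_path / f"variant{variant}.npz"
            save(c, p)
            paths.append(p)
        with np.load(paths[0]) as a, np.load(paths[1]) as b:
            lower_keys = [k for k in a.files if k.startswith("part0/")]
            assert lower_keys
            for k in lower_keys:
                assert a[k].tobytes() == b[k].tobytes()
            assert a["part1/kin_variance"] != b["part1/kin_variance"]
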