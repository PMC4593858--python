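import numpy as np
import pytest

from dgrbm import MaturationSchedule, init_rbm


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def schedule():
    return MaturationSchedule()


@pytest.fixture
def make_state(rng, schedule):
    """Factory for small RBM states of any variant."""

    def _make(n_visible=4, n_hidden=3, variant="base", seed=0, **kw):
        return init_rbm(
            n_visible, n_hidden, variant, np.random.default_rng(seed),
            schedule=schedule, **kw,
        )

    return _make


@pytest.fixture
def cd1_brute_force():
    """Independent, loop-based evaluation of the constrained CD-1 update.

    Takes the state arrays and explicit Gibbs quantities and returns the
    updated (W, a, b) computed element by element, without any vectorized
    shortcuts, for cross-checking the production implementation on toy
    networks.
    """

    def _brute(W, a, b, mask, eps, decay, cost, p, v_data, hd, v_recon, hr):
        n, nv = v_data.shape
        nh = hd.shape[1]
        W2, a2, b2 = W.copy(), a.copy(), b.copy()
        q = [sum(hd[k][j] for k in range(n)) / n for j in range(nh)]
        for i in range(nv):
            for j in range(nh):
                pos = sum(v_data[k][i] * hd[k][j] for k in range(n)) / n
                neg = sum(v_recon[k][i] * hr[k][j] for k in range(n)) / n
                W2[i, j] += eps[j] * (pos - neg) - decay[j] * W[i, j] - cost[j] * (q[j] - p)
                W2[i, j] *= mask[i, j]
        for j in range(nh):
            dpos = sum(hd[k][j] for k in range(n)) / n
            dneg = sum(hr[k][j] for k in range(n)) / n
            b2[j] += eps[j] * (dpos - dneg) - cost[j] * (q[j] - p)
        eps_mean = sum(eps) / nh
        for i in range(nv):
            vpos = sum(v_data[k][i] for k in range(n)) / n
            vneg = sum(v_recon[k][i] for k in range(n)) / n
            a2[i] += eps_mean * (vpos - vneg)
        return W2, a2, b2

    return _brute


def stub_gibbs(monkeypatch, h_probs, h_samples, v_probs, v_samples,
               h_probs2=None, h_samples2=None):
    """Force cd1_update's brief Gibbs pass to fixed states.

    ``sample_hidden`` returns (h_probs, h_samples) on the first call and
    (h_probs2, h_samples2) on the second (defaulting to the first pair);
    ``sample_visible`` always returns (v_probs, v_samples).
    """
    import dgrbm.rbm as rbm_mod

    calls = {"h": 0}

    def fake_hidden(state, v, rng):
        calls["h"] += 1
        if calls["h"] == 1:
            return np.asarray(h_probs, float), np.asarray(h_samples, float)
        return (
            np.asarray(h_probs2 if h_probs2 is not None else h_probs, float),
            np.asarray(h_samples2 if h_samples2 is not None else h_samples, float),
        )

    def fake_visible(state, h, rng):
        return np.asarray(v_probs, float), np.asarray(v_samples, float)

    monkeypatch.setattr(rbm_mod, "sample_hidden", fake_hidden)
    monkeypatch.setattr(rbm_mod, "sample_visible", fake_visible)
    return calls
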