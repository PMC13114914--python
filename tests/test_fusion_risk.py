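"""Packet gate, risk scoring, fusion MLP and time alignment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from neurotwin import fusion_risk as fr

KEY = b"pre-shared-key"
DEVICES = {"cap-01", "cap-02"}


def make_packet(ts=100.0, device="cap-01", features=(0.5, 0.6, 0.7)):
    return fr.sign_packet(
        fr.FeaturePacket(ts, device, "sess-1", np.array(features)), KEY)


class TestValidatePacket:
    def test_fresh_valid_packet_accepted(self):
        res = fr.validate_packet(make_packet(ts=100.0), KEY, now=101.0,
                                 known_devices=DEVICES)
        assert res.accepted and res.reason == "ok"

    def test_four_second_delay_is_stale(self):
        res = fr.validate_packet(make_packet(ts=100.0), KEY, now=104.0001,
                                 known_devices=DEVICES)
        assert not res.accepted and res.reason == "stale"

    def test_exactly_three_seconds_still_accepted(self):
        res = fr.validate_packet(make_packet(ts=100.0), KEY, now=103.0,
                                 known_devices=DEVICES)
        assert res.accepted

    def test_single_bit_flip_rejected(self):
        p = make_packet()
        sig = list(p.signature)
        # flip one bit of the first hex nibble
        sig[0] = format(int(sig[0], 16) ^ 1, "x")
        p.signature = "".join(sig)
        res = fr.validate_packet(p, KEY, now=101.0, known_devices=DEVICES)
        assert res.reason == "bad_hmac"

    def test_unknown_device_rejected_before_hmac(self):
        p = make_packet(device="intruder")
        res = fr.validate_packet(p, KEY, now=101.0, known_devices=DEVICES)
        assert res.reason == "unknown_device"

    def test_malformed_json_categorised(self):
        res = fr.validate_packet("{not json", KEY, now=0.0)
        assert res.reason == "malformed"

    def test_nonfinite_features_malformed(self):
        p = fr.FeaturePacket(100.0, "cap-01", "s", [np.nan, 1.0],
                             signature="0" * 64)
        res = fr.validate_packet(p, KEY, now=100.0, known_devices=DEVICES)
        assert res.reason == "malformed"

    def test_accept_implies_signature_matches_recomputation(self):
        import hashlib
        import hmac as hmac_mod
        p = make_packet()
        res = fr.validate_packet(p, KEY, now=100.5, known_devices=DEVICES)
        assert res.accepted
        assert hmac_mod.new(KEY, p.payload_bytes(),
                            hashlib.sha256).hexdigest() == p.signature

    @given(st.floats(-10, 10), st.sampled_from(["cap-01", "rogue"]))
    def test_validation_is_total(self, delay, device):
        p = make_packet(ts=100.0, device=device)
        res = fr.validate_packet(p, KEY, now=100.0 + delay,
                                 known_devices=DEVICES)
        assert res.reason in {"ok", "unknown_device", "bad_hmac", "stale",
                              "malformed"}
        assert res.accepted == (res.reason == "ok")

    def test_json_roundtrip_preserves_signature_validity(self):
        p = make_packet()
        back = fr.FeaturePacket.from_json(p.to_json())
        res = fr.validate_packet(back, KEY, now=100.1,
                                 known_devices=DEVICES)
        assert res.accepted


class TestRiskScore:
    def _identity_model(self, d=2):
        return fr.RiskModel(W=np.vstack([np.eye(1, d)[0],
                                         np.zeros(d)]),
                            b=np.zeros(2))

    def test_zero_logits_give_half_not_forwarded(self):
        m = fr.RiskModel(W=np.zeros((2, 3)), b=np.zeros(2))
        score = fr.risk_score(np.ones(3), m)
        assert score.r == pytest.approx(0.5)
        assert not score.forwarded

    def test_boundary_exactly_075_not_forwarded(self):
        # logit difference ln 3 makes R exactly 0.75
        m = fr.RiskModel(W=np.array([[1.0], [0.0]]), b=np.zeros(2))
        score = fr.risk_score(np.array([np.log(3.0)]), m)
        assert score.r == pytest.approx(0.75)
        assert not score.forwarded

    def test_softmax_closed_form(self):
        m = self._identity_model()
        score = fr.risk_score(np.array([2.0, 0.0]), m)
        assert score.r == pytest.approx(1 / (1 + np.exp(-2)))
        assert score.forwarded

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fr.risk_score(np.ones(5), self._identity_model(d=2))

    def test_forwarding_partitions_accepted_packets(self, rng):
        m = self._identity_model()
        scores = [fr.risk_score(rng.normal(size=2), m) for _ in range(100)]
        fwd = [s for s in scores if s.forwarded]
        held = [s for s in scores if not s.forwarded]
        assert len(fwd) + len(held) == 100
        assert all(s.r > 0.75 for s in fwd)
        assert all(s.r <= 0.75 for s in held)

    def test_fit_logistic_separates_synthetic_fhi_packets(self, rng):
        # low FHI -> high risk
        fhi = np.concatenate([rng.uniform(0.0, 0.35, 50),
                              rng.uniform(0.6, 1.0, 50)])
        X = fhi[:, None]
        y = (fhi < 0.5).astype(int)
        model = fr.RiskModel.fit_logistic(X, y)
        r_low = fr.risk_score(np.array([0.1]), model)
        r_high = fr.risk_score(np.array([0.9]), model)
        assert r_low.r > fr.FORWARD_THRESHOLD and r_low.forwarded
        assert r_high.r < 0.25 and not r_high.forwarded


class TestFusion:
    def test_zero_weights_return_bias_vector(self):
        mlp = fr.FusionMLP(seed=0)
        for layer in (mlp.fc1, mlp.fc2, mlp.out):
            layer.weight.data[:] = 0.0
        mlp.out.bias.data[:] = np.arange(64, dtype=float)
        state = fr.fuse(np.ones(64), np.array([0.3, 0.7]), mlp)
        assert np.allclose(state.z, np.arange(64))

    def test_concatenation_order_is_structural_first(self):
        mlp = fr.FusionMLP(seed=1)
        s = np.zeros(64)
        out_a = fr.fuse(s, np.array([1.0, 0.0]), mlp).z
        # moving the same value into the structural slot changes the input
        s2 = np.zeros(64)
        s2[0] = 1.0
        out_b = fr.fuse(s2, np.array([0.0, 0.0]), mlp).z
        assert not np.allclose(out_a, out_b)
        w = mlp.fc1.weight.data
        assert w.shape[0] == 64 + 2  # S occupies the first 64 input rows

    def test_matches_hand_matrix_arithmetic_on_toy(self, rng):
        mlp = fr.FusionMLP(seed=2, struct_dim=4)
        x = rng.normal(size=6)
        z = fr.fuse(x[:4], x[4:], mlp).z
        relu = lambda v: np.maximum(v, 0.0)
        h1 = relu(x @ mlp.fc1.weight.data + mlp.fc1.bias.data)
        h2 = relu(h1 @ mlp.fc2.weight.data + mlp.fc2.bias.data)
        expected = h2 @ mlp.out.weight.data + mlp.out.bias.data
        assert np.allclose(z, expected, atol=1e-12)

    def test_wrong_dimensions_rejected(self):
        mlp = fr.FusionMLP(seed=0)
        with pytest.raises(ValueError):
            fr.fuse(np.ones(10), np.array([0.1, 0.2]), mlp)
        with pytest.raises(ValueError):
            fr.fuse(np.ones(64), np.array([0.1, 0.2, 0.3]), mlp)

    def test_zero_logit_head_gives_half(self):
        head = fr.CompositeRiskHead(seed=0)
        head.linear.weight.data[:] = 0.0
        head.linear.bias.data[:] = 0.0
        state = fr.FusedState(z=np.ones(64), structural_embedding=np.ones(64),
                              fhv=np.array([0.5, 0.5]))
        assert fr.composite_risk(state, head) == pytest.approx(0.5)

    def test_composite_risk_bounded(self, rng):
        head = fr.CompositeRiskHead(seed=3)
        for _ in range(20):
            z = rng.normal(scale=10.0, size=64)
            state = fr.FusedState(z=z, structural_embedding=z,
                                  fhv=np.array([0.5, 0.5]))
            assert 0.0 < fr.composite_risk(state, head) < 1.0

    def test_trained_composite_risk_separates_synthetic_pairs(self, rng):
        """High risk = tumor-shifted embedding + fatigued FHV."""
        from sklearn.metrics import roc_auc_score
        n = 120
        y = np.repeat([0, 1], n // 2)
        S = rng.normal(size=(n, 64)) + 1.5 * y[:, None]
        fhv = np.column_stack([rng.uniform(0, 1, n),
                               np.where(y, rng.uniform(0, 0.4, n),
                                        rng.uniform(0.5, 1.0, n))])
        pairs = np.hstack([S, fhv])
        order = rng.permutation(n)
        pairs, y = pairs[order], y[order]
        mlp = fr.FusionMLP(seed=4)
        head = fr.CompositeRiskHead(seed=4)
        fr.train_composite_risk(pairs[:80], y[:80], mlp, head, epochs=150)
        preds = head(mlp(pairs[80:]))
        assert roc_auc_score(y[80:], preds) > 0.9


class TestAlign:
    def test_last_before_rule(self):
        idx = fr.align([50.0], [0.0, 100.0])
        assert idx[0] == 0

    def test_boundary_pairs_with_equal_timestamp(self):
        idx = fr.align([100.0], [0.0, 100.0])
        assert idx[0] == 1

    def test_fhv_before_all_scans_unpaired(self):
        idx = fr.align([-5.0], [0.0, 100.0])
        assert idx[0] == -1

    def test_empty_scan_stream_all_unpaired(self):
        idx = fr.align([1.0, 2.0], [])
        assert np.all(idx == -1)

    def test_pairing_is_monotone_in_time(self, rng):
        fhv_t = np.sort(rng.uniform(0, 100, 50))
        scan_t = np.sort(rng.uniform(0, 100, 5))
        idx = fr.align(fhv_t, scan_t)
        assert np.all(np.diff(idx) >= 0)
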