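"""Model assembly, training behavior, baselines, and dataset splitting."""

import dataclasses

import numpy as np
import pytest

import ecgrecon as er
from ecgrecon._autograd import Tensor
from ecgrecon._nn import Linear
from ecgrecon.models import (ABLATIONS, ModelConfig, build_model,
                             count_parameters, fit_lsr, predict_lead,
                             split_dataset)
from ecgrecon.segment import FRANK_LEADS, STANDARD_12_LEADS

TINY = dict(d_model=8, m=2, epochs=2, batch_size=4, seed=1, dropout=0.0,
            lr=1e-3)


def test_build_model_seed_determinism():
    a = build_model(ModelConfig(**TINY))
    b = build_model(ModelConfig(**TINY))
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb
        assert np.array_equal(pa.data, pb.data)


def test_forward_shape_contract():
    model = build_model(ModelConfig(**TINY))
    out = model(Tensor(np.zeros((2, 32, 3))), Tensor(np.zeros((2, 32, 1))),
                np.random.default_rng(0))
    assert out.data.shape == (2, 32, 1)


@pytest.mark.parametrize("ablation", ABLATIONS)
def test_all_ablations_build_and_run(ablation):
    cfg = ModelConfig(**{**TINY, "ablation": ablation})
    model = build_model(cfg)
    out = model(Tensor(np.ones((1, 32, 3))), Tensor(np.ones((1, 32, 1))),
                np.random.default_rng(0))
    assert np.isfinite(out.data).all()


def test_count_parameters_closed_form_and_monotonic():
    head = Linear(8, 1, np.random.default_rng(0))
    assert count_parameters(head) == 9  # 8 weights + bias

    small = count_parameters(build_model(ModelConfig(**TINY)))
    big = count_parameters(build_model(ModelConfig(**{**TINY, "d_model": 16})))
    assert 0 < small < big

    # closed-form sum for the vanilla encoder layer, d=8, ffn=32:
    # conv embed 3*3*8+8, three qkv + out linears 4*(64+8), two layernorms
    # 2*16, ffn 8*32+32 + 32*8+8
    enc = build_model(ModelConfig(**{**TINY, "ablation": "transformer"})).encoders[0]
    expected = (3 * 3 * 8 + 8) + 4 * (8 * 8 + 8) + 2 * (8 + 8) \
        + (8 * 32 + 32) + (32 * 8 + 8)
    assert count_parameters(enc) == expected


def _identity_pairs(n_segments, L=256, seed=0):
    """Target lead I equals input lead VX exactly (learnable mapping)."""
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_segments):
        cfg = er.SyntheticConfig(seed=int(rng.integers(1 << 30)), fs=32,
                                 duration_s=L / 32, powerline_mv=0.0,
                                 baseline_mv=0.0, white_sigma_mv=0.0)
        src = er.generate_source(cfg)
        tgt = np.tile(src.lead("VX")[:, None], (1, 12))
        pairs.append((src, er.EcgSegment(tgt, fs=32,
                                         lead_names=STANDARD_12_LEADS)))
    return pairs


def test_training_learns_identity_lead():
    mapping = er.LeadMapping(
        pairs={t: "VX" for t in STANDARD_12_LEADS}, evidence={})
    cfg = ModelConfig(d_model=16, m=2, epochs=30, batch_size=16, seed=5,
                      dropout=0.0, lr=1e-3)
    train = _identity_pairs(48, seed=1)
    val = _identity_pairs(8, seed=2)
    trained = er.train_lead_model(train, val, "I", mapping, cfg)
    preds = predict_lead(trained, [s for s, _ in val])
    prs = [er.pearson_r(preds[k], val[k][1].lead("I")) for k in range(len(val))]
    assert np.mean(prs) >= 0.99
    assert trained.best_epoch <= cfg.epochs
    assert trained.min_val_loss >= 0


def test_training_reproducible_and_epoch_bookkeeping():
    mapping = er.LeadMapping(
        pairs={t: "VX" for t in STANDARD_12_LEADS}, evidence={})
    cfg = ModelConfig(d_model=8, m=2, epochs=2, batch_size=4, seed=9,
                      dropout=0.1, lr=1e-3)
    train = _identity_pairs(8, L=128, seed=3)
    val = _identity_pairs(2, L=128, seed=4)
    a = er.train_lead_model(train, val, "II", mapping, cfg)
    b = er.train_lead_model(train, val, "II", mapping, cfg)
    assert a.train_losses == b.train_losses
    assert a.val_losses == b.val_losses

    one = er.train_lead_model(train, val, "II", mapping,
                              dataclasses.replace(cfg, epochs=1))
    assert one.best_epoch == 1


def test_loss_decreases_early_for_every_ablation():
    mapping = er.LeadMapping(
        pairs={t: "VX" for t in STANDARD_12_LEADS}, evidence={})
    train = _identity_pairs(8, L=128, seed=6)
    val = _identity_pairs(2, L=128, seed=7)
    for ablation in ABLATIONS:
        cfg = ModelConfig(d_model=8, m=2, epochs=5, batch_size=8, seed=2,
                          dropout=0.0, lr=1e-3, ablation=ablation)
        trained = er.train_lead_model(train, val, "I", mapping, cfg)
        assert trained.train_losses[-1] < trained.train_losses[0]


def test_reconstruct_12lead_covers_and_orders_leads(noiseless_dataset):
    ds = noiseless_dataset
    pairs = ds.pairs(ds.records[:2])
    mapping = er.default_lead_mapping()
    cfg = ModelConfig(d_model=8, m=2, epochs=1, batch_size=4, seed=3,
                      dropout=0.0, lr=1e-3)
    models = {lead: er.train_lead_model(pairs, pairs[:2], lead, mapping, cfg)
              for lead in STANDARD_12_LEADS}
    out = er.reconstruct_12lead(models, pairs[0][0])
    assert out.lead_names == STANDARD_12_LEADS
    out2 = er.reconstruct_12lead(models, pairs[0][0])
    assert np.array_equal(out.samples, out2.samples)
    with pytest.raises(ValueError, match="V6"):
        er.reconstruct_12lead({k: v for k, v in models.items() if k != "V6"},
                              pairs[0][0])


def _affine_pairs(weights, intercepts, n=300, segments=2, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(segments):
        src = rng.standard_normal((n, 3))
        tgt = src @ np.asarray(weights).T + np.asarray(intercepts)
        pairs.append((er.EcgSegment(src, fs=250, lead_names=FRANK_LEADS),
                      er.EcgSegment(tgt, fs=250,
                                    lead_names=STANDARD_12_LEADS)))
    return pairs


def test_fit_lsr_recovers_exact_affine_map():
    w = np.zeros((12, 3))
    w[0] = (2.0, -1.0, 0.0)
    b = np.zeros(12)
    b[1] = 0.5
    w[1] = (1.0, 0.0, 0.0)
    tm = fit_lsr(_affine_pairs(w, b))
    assert np.allclose(tm.coefficients[0], [2.0, -1.0, 0.0, 0.0], atol=1e-9)
    assert tm.coefficients[1, 3] == pytest.approx(0.5, abs=1e-9)


def test_fit_lsr_matches_normal_equations_oracle(rng):
    w = rng.standard_normal((12, 3))
    b = rng.standard_normal(12)
    pairs = _affine_pairs(w, b, seed=5)
    noisy = [(s, t.with_samples(t.samples + 0.1 * rng.standard_normal(t.samples.shape)))
             for s, t in pairs]
    tm = fit_lsr(noisy)
    X = np.vstack([np.column_stack([s.samples, np.ones(s.n_samples)])
                   for s, _ in noisy])
    Y = np.vstack([t.samples for _, t in noisy])
    beta = np.linalg.solve(X.T @ X, X.T @ Y)  # hand-coded normal equations
    assert np.abs(tm.coefficients - beta.T).max() < 1e-8


def test_apply_matrix_exactness_and_oracle(rng):
    w = rng.standard_normal((12, 3))
    b = rng.standard_normal(12)
    pairs = _affine_pairs(w, b, seed=6)
    tm = fit_lsr(pairs)
    for src, tgt in pairs:
        pred = er.apply_matrix(tm, src)
        assert np.abs(pred.samples - tgt.samples).max() < 1e-9
    x = pairs[0][0]
    direct = x.samples @ tm.coefficients[:, :3].T + tm.coefficients[:, 3]
    assert np.array_equal(er.apply_matrix(tm, x).samples, direct)


def test_transform_matrix_csv_roundtrip(tmp_path, rng):
    tm = fit_lsr(_affine_pairs(rng.standard_normal((12, 3)),
                               rng.standard_normal(12), seed=7))
    tm.to_csv(tmp_path / "m.csv")
    back = er.TransformMatrix.from_csv(tmp_path / "m.csv")
    assert np.abs(back.coefficients - tm.coefficients).max() < 1e-12


class _Rec:
    def __init__(self, sid, label=""):
        self.subject_id = sid
        self.label = label


def test_split_sizes_and_subject_disjointness():
    recs = [_Rec(f"s{i}") for i in range(5)]
    tr, va, te = split_dataset(recs, (3, 1, 1), seed=0)
    assert (len(tr), len(va), len(te)) == (3, 1, 1)

    recs = [_Rec(f"s{i % 20}") for i in range(60)]
    for seed in range(100):
        parts = split_dataset(recs, (3, 1, 1), seed=seed)
        ids = [set(r.subject_id for r in p) for p in parts]
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])


def test_split_stratified_allocation():
    recs = ([_Rec(f"a{i}", "healthy") for i in range(5)]
            + [_Rec(f"b{i}", "mi") for i in range(5)])
    tr, va, te = split_dataset(recs, (3, 1, 1), seed=1,
                               label_of=lambda r: r.label)
    # hand-computed: each 5-subject class splits 3/1/1
    for part, n in zip((tr, va, te), (3, 1, 1)):
        labels = [r.label for r in part]
        assert labels.count("healthy") == n
        assert labels.count("mi") == n

    with pytest.raises(ValueError):
        split_dataset([_Rec("only")], (3, 1, 1), seed=0)
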