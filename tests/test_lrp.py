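import numpy as np
import pytest

from charqsar.lrp import (LayerLedgerRow, applicability_flag, atom_attribution,
                          lrp_conv, lrp_dense, lrp_highway, lrp_maxpool,
                          map_chars_to_atoms, propagate, propagate_trace)
from charqsar.qsar_textcnn import CnnHeadConfig, QsarModel, build_head


class TestDenseRule:
    def test_proportional_split_zero_bias(self):
        r_in, bias = lrp_dense(np.array([5.0]), np.array([[1.0], [1.0]]),
                               np.array([0.0]), np.array([2.0, 3.0]))
        assert np.allclose(r_in, [2.0, 3.0])
        assert bias == pytest.approx(0.0, abs=1e-8)

    def test_bias_absorption_hand_example(self):
        # z = 2 + 3 + 1 = 6; R_i = x_i * 1 / 6 * 6 = x_i; bias takes 1
        r_in, bias = lrp_dense(np.array([6.0]), np.array([[1.0], [1.0]]),
                               np.array([1.0]), np.array([2.0, 3.0]))
        assert np.allclose(r_in, [2.0, 3.0])
        assert bias == pytest.approx(1.0, abs=1e-8)

    def test_conservation_random_layers(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_in, n_out = rng.integers(2, 9, size=2)
            w = rng.normal(size=(n_in, n_out))
            b = rng.normal(size=n_out)
            x = rng.normal(size=n_in)
            r_out = rng.normal(size=n_out)
            r_in, bias = lrp_dense(r_out, w, b, x)
            assert r_out.sum() == pytest.approx(r_in.sum() + bias, rel=1e-6)


class TestConvRule:
    def test_kernel_one_reduces_to_dense(self):
        rng = np.random.default_rng(1)
        D, F, L = 4, 3, 6
        kernel = rng.normal(size=(1, D, F))
        b = rng.normal(size=F)
        x = rng.normal(size=(L, D))
        r_out = rng.normal(size=(L, F))
        r_conv, bias_c = lrp_conv(r_out, kernel, b, x)
        r_dense = np.zeros_like(x)
        bias_d = 0.0
        for i in range(L):
            ri, bi = lrp_dense(r_out[i], kernel[0], b, x[i])
            r_dense[i] = ri
            bias_d += bi
        assert np.allclose(r_conv, r_dense, atol=1e-9)
        assert bias_c == pytest.approx(bias_d)

    def test_zero_bias_exact_conservation(self):
        rng = np.random.default_rng(2)
        kernel = rng.normal(size=(3, 4, 5))
        x = rng.normal(size=(10, 4))
        r_out = rng.normal(size=(8, 5))
        r_in, bias = lrp_conv(r_out, kernel, np.zeros(5), x)
        assert bias == pytest.approx(0.0, abs=1e-6)
        assert r_in.sum() == pytest.approx(r_out.sum(), rel=1e-6)

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_matches_unfolded_dense_oracle(self, k):
        """Brute force: materialize the conv as one big dense layer over the
        flattened input and compare relevances."""
        rng = np.random.default_rng(10 + k)
        D, F, L = 3, 4, 12
        W = L - k + 1
        kernel = rng.normal(size=(k, D, F))
        b = rng.normal(size=F)
        x = rng.normal(size=(L, D))
        r_out = rng.normal(size=(W, F))

        big_w = np.zeros((L * D, W * F))
        big_b = np.zeros(W * F)
        for w_pos in range(W):
            for f in range(F):
                col = w_pos * F + f
                big_b[col] = b[f]
                for j in range(k):
                    big_w[(w_pos + j) * D:(w_pos + j + 1) * D, col] = kernel[j, :, f]
        r_flat, bias_flat = lrp_dense(r_out.reshape(-1), big_w, big_b,
                                      x.reshape(-1))
        r_in, bias = lrp_conv(r_out, kernel, b, x)
        assert np.allclose(r_in, r_flat.reshape(L, D), atol=1e-6)
        assert bias == pytest.approx(bias_flat, abs=1e-6)


class TestMaxPoolRule:
    def test_winner_take_all(self):
        r_in = lrp_maxpool(np.array([1.0]),
                           np.array([[0.2], [0.9], [0.1]]))
        assert np.allclose(r_in[:, 0], [0.0, 1.0, 0.0])

    def test_tie_break_first_index(self):
        r_in = lrp_maxpool(np.array([1.0]),
                           np.array([[0.9], [0.9], [0.1]]))
        assert np.allclose(r_in[:, 0], [1.0, 0.0, 0.0])

    def test_always_conserves(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            inputs = rng.normal(size=(rng.integers(2, 10), rng.integers(1, 6)))
            r_out = rng.normal(size=inputs.shape[1])
            assert lrp_maxpool(r_out, inputs).sum() == pytest.approx(r_out.sum())


class TestHighwayRule:
    def test_gate_one_all_to_transform(self):
        r_t, r_c = lrp_highway(np.array([2.0]), np.array([1.0]),
                               np.array([3.0]), np.array([5.0]))
        assert r_t[0] == pytest.approx(2.0) and r_c[0] == pytest.approx(0.0)

    def test_gate_zero_all_to_carry(self):
        r_t, r_c = lrp_highway(np.array([2.0]), np.array([0.0]),
                               np.array([3.0]), np.array([5.0]))
        assert r_t[0] == pytest.approx(0.0) and r_c[0] == pytest.approx(2.0)

    def test_hand_split_14_17(self):
        # contributions 0.7*2 = 1.4 and 0.3*1 = 0.3 -> split 14/17, 3/17
        r_t, r_c = lrp_highway(np.array([1.0]), np.array([0.7]),
                               np.array([2.0]), np.array([1.0]))
        assert r_t[0] == pytest.approx(14 / 17)
        assert r_c[0] == pytest.approx(3 / 17)

    def test_exact_conservation(self):
        rng = np.random.default_rng(4)
        g = rng.random(16)
        h = rng.normal(size=16)
        x = rng.normal(size=16)
        r = rng.normal(size=16)
        r_t, r_c = lrp_highway(r, g, h, x)
        assert (r_t + r_c).sum() == pytest.approx(r.sum(), rel=1e-6)


def _random_head_and_input(seed, task="regression"):
    rng = np.random.default_rng(seed)
    ks = tuple(sorted(rng.choice([1, 2, 3, 4, 5], size=rng.integers(2, 4),
                                 replace=False).tolist()))
    fs = tuple(int(f) for f in rng.integers(2, 7, size=len(ks)))
    cfg = CnnHeadConfig(kernel_sizes=ks, filter_counts=fs,
                        dense_width=int(rng.integers(4, 12)), task=task,
                        seed=int(seed))
    d = int(rng.integers(2, 7))
    head = build_head(cfg, d_model=d)
    # give every layer a non-trivial bias so absorption is exercised
    for p in (head.conv_b + [head.dense.b, head.hw_t.b, head.hw_h.b, head.out.b]):
        p.data += rng.normal(0, 0.3, size=p.data.shape)
    x = rng.normal(size=(int(rng.integers(3, 12)), d))
    return head, x


class TestPropagate:
    def test_ledger_chains_and_totals(self, trained_qsar_model):
        rel, ledger = propagate(trained_qsar_model, "CC(Cl)CO")
        names = [r.layer for r in ledger]
        assert names[0] == "Result" and names[-1] == "Total"
        assert "HighWay Output" in names and "DeMaxPool" in names
        # consecutive rows chain: upper of next == lower of previous
        for a, b in zip(ledger[1:3], ledger[2:4]):
            assert b.r_upper == pytest.approx(a.r_lower)
        total = ledger[-1]
        assert total.delta == pytest.approx(total.r_upper - total.r_lower)
        assert rel.total == pytest.approx(total.r_lower)

    def test_conservation_on_random_heads(self):
        for seed in range(30):
            head, x = _random_head_and_input(seed)
            trace = head.forward_trace(x)
            _, ledger = propagate_trace(head, trace, neuron=0)
            rows = {r.layer: r for r in ledger}
            # per-step conservation: delta accounts exactly for what each
            # backward step absorbed, and the chain is contiguous
            chain = [rows["Result"].r_upper]
            for name in ["HighWay Output", "HighWay Input", "DeMaxPool"]:
                assert rows[name].r_upper == pytest.approx(chain[-1], rel=1e-6, abs=1e-9)
                chain.append(rows[name].r_lower)
            conv_upper = sum(r.r_upper for r in ledger if r.layer.startswith("Conv"))
            assert conv_upper == pytest.approx(rows["DeMaxPool"].r_lower,
                                               rel=1e-6, abs=1e-9)

    def test_bias_free_head_conserves_to_total(self):
        head, x = _random_head_and_input(99)
        for p in (head.conv_b + [head.dense.b, head.hw_h.b, head.out.b]):
            p.data[:] = 0.0
        trace = head.forward_trace(x)
        _, ledger = propagate_trace(head, trace, neuron=0)
        total = [r for r in ledger if r.layer == "Total"][0]
        if total.r_upper != 0:
            assert abs(total.bias_pct) < 1e-6

    def test_classification_propagates_positive_neuron(self, tiny_encoder):
        cfg = CnnHeadConfig(kernel_sizes=(1, 2), filter_counts=(4, 4),
                            task="classification")
        model = QsarModel(encoder=tiny_encoder,
                          head=build_head(cfg, tiny_encoder.config.d_model),
                          config=cfg)
        _, ledger = propagate(model, "CC(Cl)CO")
        trace = model.head.forward_trace(
            __import__("charqsar.embedding", fromlist=["extract_embedding"])
            .extract_embedding(model.encoder, "CC(Cl)CO").matrix)
        assert ledger[0].r_upper == pytest.approx(float(trace["output"][1]))


class TestLedgerRows:
    def test_row_identities(self):
        row = LayerLedgerRow.make("X", 2.0, 1.5)
        assert row.delta == pytest.approx(0.5)
        assert row.bias_pct == pytest.approx(25.0)

    def test_zero_upper(self):
        assert LayerLedgerRow.make("X", 0.0, 0.0).bias_pct == 0.0


class TestApplicability:
    def _ledger(self, upper, lower):
        return [LayerLedgerRow.make("Result", upper, upper),
                LayerLedgerRow.make("Total", upper, lower)]

    def test_reference_case_ok(self):
        # 75.4% propagated
        assert applicability_flag(self._ledger(0.98119, 0.7398)) == "ok"

    def test_forty_percent_warns(self):
        assert applicability_flag(self._ledger(1.0, 0.4)) == "warning"

    def test_boundary_fifty_percent_ok(self):
        assert applicability_flag(self._ledger(1.0, 0.5)) == "ok"

    def test_no_total_row_rejected(self):
        with pytest.raises(ValueError):
            applicability_flag([LayerLedgerRow.make("Result", 1.0, 1.0)])


class TestCharAtomMap:
    def test_bromobenzene(self):
        cmap = map_chars_to_atoms("Brc1ccccc1")
        assert cmap.elements[0] == "Br"
        assert cmap.spans[0] == (0, 1)
        # ring-opening digit folds into the first aromatic carbon,
        # closing digit into the last
        assert cmap.spans[1] == (2, 3)
        assert cmap.spans[-1] == (8, 9)
        assert len(cmap.spans) == 7

    def test_bracket_atom_owns_brackets(self):
        cmap = map_chars_to_atoms("[O-]")
        assert len(cmap.spans) == 1
        assert cmap.spans[0] == (0, 1, 2, 3)

    def test_two_letter_elements(self):
        cmap = map_chars_to_atoms("ClCCBr")
        assert cmap.elements == ("Cl", "C", "C", "Br")

    def test_syntax_folds_to_preceding_atom(self):
        cmap = map_chars_to_atoms("CC(=O)O")
        flat = sorted(i for span in cmap.spans for i in span)
        assert flat == list(range(7))
        # '(' and '=' fold into the atoms before them
        assert 2 in cmap.spans[1]
        assert 3 in cmap.spans[2] or 3 in cmap.spans[1]

    def test_partition_property_on_toolkit_smiles(self, rdkit_oracle):
        from rdkit import Chem
        seeds = ["CC(=O)Oc1ccccc1C(=O)O", "O=[N+]([O-])c1ccc(Br)cc1",
                 "C[C@H](N)C(=O)O", "c1ccc2ccccc2c1", "CC(C)(C)c1ccccc1O"]
        count = 0
        for base in seeds:
            for i in range(40):
                s = rdkit_oracle.random_variant(base, seed=i + 1)
                cmap = map_chars_to_atoms(s)
                flat = [i for span in cmap.spans for i in span]
                flat += list(cmap.syntax_only)
                assert sorted(flat) == list(range(len(s))), s
                assert len(flat) == len(set(flat))
                assert len(cmap.spans) == Chem.MolFromSmiles(s).GetNumHeavyAtoms(), s
                count += 1
        assert count == 200


class TestAtomAttribution:
    def test_benzene_six_atoms(self, tiny_encoder, rdkit_oracle):
        cfg = CnnHeadConfig(kernel_sizes=(1, 3), filter_counts=(4, 4))
        model = QsarModel(encoder=tiny_encoder,
                          head=build_head(cfg, tiny_encoder.config.d_model),
                          config=cfg)
        attr = atom_attribution(model, "c1ccccc1", rdkit_oracle)
        assert attr.n_rooted == 6
        assert len(attr.contributions) == 6

    def test_bromonitrobenzene_ten_atoms(self, tiny_encoder, rdkit_oracle):
        cfg = CnnHeadConfig(kernel_sizes=(1, 2), filter_counts=(4, 4))
        model = QsarModel(encoder=tiny_encoder,
                          head=build_head(cfg, tiny_encoder.config.d_model),
                          config=cfg)
        attr = atom_attribution(model, "O=[N+]([O-])c1ccc(Br)cc1", rdkit_oracle)
        assert attr.n_rooted == 10
        assert len(attr.contributions) == 10
        assert all(np.isfinite(attr.contributions))

    def test_contribution_sum_tracks_propagated_relevance(self, trained_qsar_model,
                                                          grammar_oracle):
        attr = atom_attribution(trained_qsar_model, "CC(Cl)CO", grammar_oracle)
        assert attr.n_rooted == 5
        assert np.isfinite(attr.mean_bias_pct)
        assert len(attr.flags) == 5

    def test_planted_halogen_ranks_above_carbon(self, trained_qsar_model,
                                                grammar_oracle):
        # model was trained on y = 2 * halogen count (conftest)
        wins = 0
        probes = ["CC(Cl)CO", "BrCCC", "CC(F)(Cl)C", "ClCC(C)N"]
        for s in probes:
            attr = atom_attribution(trained_qsar_model, s, grammar_oracle)
            from charqsar.synthetic_fixtures import HALOGENS, parse_acyclic_smiles
            elements, _ = parse_acyclic_smiles(s)
            c = np.asarray(attr.contributions)
            hal = [i for i, e in enumerate(elements) if e in HALOGENS]
            car = [i for i, e in enumerate(elements) if e == "C"]
            wins += c[hal].mean() > c[car].mean()
        assert wins >= 3
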