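"""Descriptor-family correctness against independent brute-force oracles.

The oracles below recompute each family with naive dictionary/loop code,
independent of the vectorized implementations.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqtox._aadata import ALPHABET, CTD_PROPERTIES, TRIAD_CLASSES
from seqtox import descriptors as D

from conftest import make_dataset

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def aac_bf(seq):
    return {aa: seq.count(aa) / len(seq) for aa in ALPHABET}


def dpc_bf(seq):
    pairs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    return {a + b: pairs.count(a + b) / len(pairs) for a in ALPHABET for b in ALPHABET}


def ctd_bf(seq):
    out = {}
    L = len(seq)
    for p, (name, groups) in enumerate(CTD_PROPERTIES, start=1):
        cls = [next(g for g, mem in enumerate(groups, 1) if aa in mem) for aa in seq]
        for g in (1, 2, 3):
            out[f"{name}.Group{g}"] = cls.count(g) / L
        for g1, g2, tag in ((1, 2, "Tr1221"), (1, 3, "Tr1331"), (2, 3, "Tr2332")):
            n = sum(
                1
                for a, b in zip(cls, cls[1:])
                if (a, b) in ((g1, g2), (g2, g1))
            )
            out[f"prop{p}.{tag}"] = n / (L - 1) if L > 1 else 0.0
        for g in (1, 2, 3):
            pos = [i + 1 for i, c in enumerate(cls) if c == g]
            if not pos:
                vals = [0.0] * 5
            else:
                n = len(pos)
                picks = [1, max(1, round(0.25 * n)), max(1, round(0.5 * n)),
                         max(1, round(0.75 * n)), n]
                vals = [pos[k - 1] / L * 100 for k in picks]
            for frac, v in zip((0, 25, 50, 75, 100), vals):
                out[f"prop{p}.G{g}.residue{frac}"] = v
    return out


def ctriad_bf(seq):
    cls = {aa: i + 1 for i, mem in enumerate(TRIAD_CLASSES) for aa in mem}
    windows = [seq[i : i + 3] for i in range(len(seq) - 2)]
    out = {f"VS{i}{j}{k}": 0 for i in range(1, 8) for j in range(1, 8) for k in range(1, 8)}
    for w in windows:
        out[f"VS{cls[w[0]]}{cls[w[1]]}{cls[w[2]]}"] += 1
    return {k: v / len(windows) for k, v in out.items()}


# ---------------------------------------------------------------------------
# oracle-equivalence tests
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "family, oracle, min_len",
    [
        (D.aac, aac_bf, 1),
        (D.dpc, dpc_bf, 2),
        (D.ctd, ctd_bf, 1),
        (D.conjoint_triad, ctriad_bf, 3),
    ],
    ids=["aac", "dpc", "ctd", "ctriad"],
)
def test_descriptors_match_brute_force_enumeration(
    family, oracle, min_len, exhaustive_short_sequences, random_sequences
):
    for seq in exhaustive_short_sequences + random_sequences[:25]:
        if len(seq) < min_len:
            continue
        got = family(seq)
        expected = oracle(seq)
        assert set(got.index) == set(expected)
        for name, value in expected.items():
            assert got[name] == pytest.approx(value, abs=1e-12), (seq, name)


# ---------------------------------------------------------------------------
# closed-form / limit checks
# ---------------------------------------------------------------------------


def test_aac_symmetry_and_homopolymer():
    assert D.aac("AAAA")["A"] == 1.0
    assert D.aac("AAAA").drop("A").sum() == 0.0
    uniform = D.aac(ALPHABET)
    assert np.allclose(uniform.to_numpy(), 0.05)


def test_dpc_and_triad_preconditions():
    with pytest.raises(ValueError):
        D.dpc("A")
    with pytest.raises(ValueError):
        D.conjoint_triad("AC")


def test_ctd_homopolymer_has_no_transitions():
    s = D.ctd("AAAAAAAA")
    assert all(s[n] == 0 for n in s.index if ".Tr" in n)


def test_length3_sequence_has_exactly_one_triad():
    s = D.conjoint_triad("ACD")
    assert (s > 0).sum() == 1
    assert s.sum() == pytest.approx(1.0)


def test_moreau_broto_on_homopolymer_equals_squared_normalized_value():
    table = D.default_aaindex_table()
    acc = "CIDH920105"
    v = table[acc]
    c = (v - v.mean()) / v.std()
    expected = c[ALPHABET.index("W")] ** 2
    s = D.autocorrelation("W" * 40, "moreau-broto", (acc,), nlag=5, table=table)
    assert np.allclose(s.to_numpy(), expected)


def test_geary_and_moran_on_constant_profile_guard_to_zero():
    for method in ("geary", "moran"):
        s = D.autocorrelation("W" * 40, method, nlag=5)
        assert np.allclose(s.to_numpy(), 0.0)


def test_autocorrelation_dimensions_and_length_guard():
    s = D.autocorrelation("ACDEFGHIKLMNPQRSTVWY" * 2, "moran", nlag=30)
    assert len(s) == 8 * 30
    with pytest.raises(ValueError, match="length > nlag"):
        D.autocorrelation("ACDEFG", nlag=30)


def test_socn_matches_direct_summation_on_two_letter_toy():
    seq = "ACACACACAC" * 4
    nlag = 3
    s = D.qso_socn(seq, nlag=nlag)
    M = D._DIST_MATRICES["Schneider"]
    a, c = ALPHABET.index("A"), ALPHABET.index("C")
    for d in range(1, nlag + 1):
        expected = sum(
            M[
                a if i % 2 == 0 else c,
                a if (i + d) % 2 == 0 else c,
            ]
            ** 2
            for i in range(len(seq) - d)
        )
        assert s[f"Schneider.lag{d}"] == pytest.approx(expected)


def test_qso_weight_zero_reduces_to_composition(random_sequences):
    seq = random_sequences[0]
    s = D.qso_socn(seq, nlag=5, w=0.0)
    comp = D.aac(seq)
    for mat in ("Schneider", "Grantham"):
        got = s[[f"{mat}.Xr.{aa}" for aa in ALPHABET]].to_numpy()
        assert np.allclose(got, comp.to_numpy())


def test_paac_lambda_zero_equals_composition():
    seq = "ACDEFGHIKLMNPQRSTVWY"
    s = D.paac_apaac(seq, lam=0)
    assert np.allclose(s[[f"Xc1.{aa}" for aa in ALPHABET]].to_numpy(), 0.05)


def test_paac_homopolymer_has_zero_order_correlation():
    s = D.paac_apaac("W" * 50, lam=5)
    assert np.allclose(s[[f"Xc2.lambda.{d}" for d in range(1, 6)]].to_numpy(), 0.0)


def test_paac_apaac_dimensions():
    s = D.paac_apaac("ACDEFGHIKLMNPQRSTVWY" * 2, lam=30)
    assert sum(n.startswith("Xc") for n in s.index) == 50
    assert sum(n.startswith("Pc") for n in s.index) == 80


def test_aaindex_profile_is_sequence_mean():
    table = D.AAIndexTable({"TOY": np.zeros(20)})
    table.indices["TOY"][ALPHABET.index("A")] = 1.0
    table.indices["TOY"][ALPHABET.index("C")] = 2.0
    table.indices["TOY"][ALPHABET.index("D")] = 6.0
    assert D.aaindex_profile("ACD", table)["TOY"] == pytest.approx(3.0)
    assert D.aaindex_profile("A", table)["TOY"] == pytest.approx(1.0)


def test_aaindex_table_parsing_skips_na_records(tmp_path):
    path = tmp_path / "mini.aaindex"
    path.write_text(
        "H GOOD00001\nI  A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V\n"
        "  1 2 3 4 5 6 7 8 9 10\n  11 12 13 14 15 16 17 18 19 20\n//\n"
        "H BAD000001\nI  A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V\n"
        "  1 2 3 4 5 6 7 8 9 10\n  11 12 13 14 15 16 17 18 NA 20\n//\n"
    )
    table = D.AAIndexTable.from_file(path)
    assert table.accessions() == ["GOOD00001"]
    assert table["GOOD00001"][ALPHABET.index("A")] == 1.0
    assert table["GOOD00001"][ALPHABET.index("V")] == 20.0


def test_aa_group_counts_partition_the_sequence(random_sequences):
    s = D.aa_groups_length("DDEE")
    assert s["count_negative"] == 4 and s["length"] == 4
    assert s.drop(["count_negative", "length"]).sum() == 0
    assert D.aa_groups_length("GPGP")["count_conformational"] == 4
    for seq in random_sequences[:10]:
        s = D.aa_groups_length(seq)
        assert s.drop("length").sum() == len(seq) == s["length"]


@settings(max_examples=40, deadline=None)
@given(st.text(alphabet=ALPHABET, min_size=2, max_size=60))
def test_composition_families_sum_to_one(seq):
    assert D.aac(seq).sum() == pytest.approx(1.0, abs=1e-9)
    assert D.dpc(seq).sum() == pytest.approx(1.0, abs=1e-9)


@settings(max_examples=25, deadline=None)
@given(st.text(alphabet=ALPHABET, min_size=1, max_size=60))
def test_ctd_distribution_values_are_ordered_percentiles(seq):
    s = D.ctd(seq)
    for p in range(1, 8):
        for g in (1, 2, 3):
            vals = [s[f"prop{p}.G{g}.residue{f}"] for f in (0, 25, 50, 75, 100)]
            assert all(0 <= v <= 100 for v in vals)
            if vals[0] > 0:  # class occurs
                assert vals == sorted(vals)


# ---------------------------------------------------------------------------
# featurize driver
# ---------------------------------------------------------------------------


def test_featurize_dimensions_and_determinism(random_sequences):
    from seqtox.motif_mining import MotifSet

    seqs = random_sequences[:4] + [random_sequences[0]]
    ds = make_dataset(seqs)
    ms = MotifSet(["CKN", "WCG"], {"CKN": 1, "WCG": 1})
    fm = D.featurize(ds, motif_set=ms)
    protr = fm.shape[1] - 20 - 7 - 2 - 16  # minus PSSM, groups, motifs, aaindex
    assert protr == 1920
    # identical sequences give identical rows
    assert np.array_equal(fm.iloc[0].to_numpy(), fm.iloc[4].to_numpy())
    fm2 = D.featurize(ds, motif_set=ms)
    assert fm.equals(fm2)


def test_featurize_without_aaindex_yields_1997_columns(random_sequences):
    from seqtox.motif_mining import MotifSet

    ds = make_dataset(random_sequences[:2])
    config = D.DescriptorConfig(
        families=tuple(f for f in D._ALL_FAMILIES if f != "aaindex")
    )
    motifs = [f"QW{a}{b}" for a in ALPHABET[:10] for b in ALPHABET[:5]]
    ms = MotifSet(motifs, {m: 1 for m in motifs})
    assert len(ms) == 50
    fm = D.featurize(ds, config, motif_set=ms)
    assert fm.shape[1] == 1997


def test_featurize_attaches_sequence_id_to_errors():
    ds = make_dataset(["ACDEFGHIKLM"])  # shorter than default nlag
    with pytest.raises(ValueError, match="s0"):
        D.featurize(ds)


def test_manifest_names_resolve_uniquely(random_sequences):
    ds = make_dataset(random_sequences[:1])
    fm = D.featurize(ds)
    manifest = D.load_feature_manifest()
    resolved = D.resolve_manifest(manifest, fm.columns)
    assert len(resolved) == 88
    assert len(set(resolved.values())) == 88
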