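"""Discriminative k-mer index and confidence classification.

The index builder is checked against a brute-force dictionary oracle that
applies the filtering rules literally on toy targets.
"""
import numpy as np
import pytest

from bacatlas import arm_classifier as armc
from bacatlas._kmers import kmer_codes, revcomp
from bacatlas.errors import ConfigurationError, DataError
from bacatlas.synthetic import BacAssembly


def brute_force_index(targets: dict, k: int, min_count: int, canonical: bool):
    """Literal filtering-rule oracle: enumerate every k-mer of every target,
    apply within-target rarity, single-target uniqueness, and the
    S/L-arms-of-one-chromosome centromeric exception."""

    def canon(w):
        return min(w, revcomp(w)) if canonical else w

    per_target = {}
    for label, seqs in targets.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        counts = {}
        for s in seqs:
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                if any(c not in "ACGT" for c in w):
                    continue
                w = canon(w)
                counts[w] = counts.get(w, 0) + 1
        per_target[label] = {w for w, c in counts.items() if c >= min_count}

    owners = {}
    for label, kmers in per_target.items():
        for w in kmers:
            owners.setdefault(w, []).append(label)
    result = {}
    for w, labs in owners.items():
        if len(labs) == 1:
            result[w] = labs[0]
        elif len(labs) == 2:
            a, b = sorted(labs)
            if a[:-1] == b[:-1] and {a[-1], b[-1]} == {"S", "L"}:
                result[w] = a[:-1] + "C"
    return result


def index_as_dict(index: armc.KmerIndex) -> dict:
    def decode(code, k):
        letters = []
        for _ in range(k):
            letters.append("ACGT"[code & 3])
            code >>= 2
        return "".join(reversed(letters))

    return {
        decode(int(km), index.k): index.labels[int(lc)]
        for km, lc in zip(index.kmers, index.label_codes)
    }


@pytest.fixture(scope="module")
def toy_targets():
    rng = np.random.default_rng(42)
    draw = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    centromere = draw(5_000)
    arm_s = draw(12_000) + centromere
    arm_l = centromere + draw(15_000)
    return {
        "1H": draw(20_000),
        "4HS": arm_s,
        "4HL": arm_l,
        "5HS": draw(8_000),
        "5HL": draw(9_000),
    }


def test_index_equals_brute_force_oracle(toy_targets):
    cfg = armc.ClassifierConfig(k=19, min_kmer_count=1)
    index = armc.build_index(toy_targets, cfg)
    oracle = brute_force_index(toy_targets, k=19, min_count=1, canonical=True)
    assert index_as_dict(index) == oracle


def test_shared_segment_kmers_get_centromeric_label(toy_targets):
    cfg = armc.ClassifierConfig(k=19, min_kmer_count=1)
    index = armc.build_index(toy_targets, cfg)
    counts = index.label_counts()
    assert counts["4HC"] > 4_000  # ~5 kb shared segment
    assert counts.get("5HC", 0) == 0  # no shared segment between 5HS/5HL


def test_kmer_in_three_targets_is_discarded():
    shared = "ACGTACGTACGTACGTACG"  # one 19-mer
    targets = {
        "4HS": "A" * 30 + shared,
        "4HL": shared + "C" * 30,
        "5HS": "G" * 30 + shared,
        "5HL": "T" * 40,
    }
    index = armc.build_index(targets, armc.ClassifierConfig(k=19, min_kmer_count=1))
    assert shared not in index_as_dict(index)


def test_rare_kmers_discarded_by_min_count():
    # every 19-mer occurs once per target; min_kmer_count=2 empties the index
    rng = np.random.default_rng(1)
    targets = {
        "2HS": "".join(rng.choice(list("ACGT"), size=2_000)),
        "2HL": "".join(rng.choice(list("ACGT"), size=2_000)),
    }
    assert len(armc.build_index(targets, armc.ClassifierConfig(k=19, min_kmer_count=2))) == 0
    assert len(armc.build_index(targets, armc.ClassifierConfig(k=19, min_kmer_count=1))) > 0


def test_empty_target_rejected():
    with pytest.raises(ConfigurationError):
        armc.build_index({"A": "", "B": "ACGT"}, armc.ClassifierConfig(k=3))
    with pytest.raises(ConfigurationError):
        armc.build_index({"A": "ACGTACGT"}, armc.ClassifierConfig(k=3))


def test_index_save_load_roundtrip(tmp_path, toy_targets):
    cfg = armc.ClassifierConfig(k=19, min_kmer_count=1)
    index = armc.build_index(toy_targets, cfg)
    path = tmp_path / "idx.bin"
    index.save(path)
    loaded = armc.KmerIndex.load(path)
    assert loaded.labels == index.labels
    assert np.array_equal(loaded.kmers, index.kmers)
    assert np.array_equal(loaded.label_codes, index.label_codes)
    with pytest.raises(DataError, match="magic"):
        bad = tmp_path / "junk.bin"
        bad.write_bytes(b"not an index")
        armc.KmerIndex.load(bad)


class TestClassify:
    cfg3 = armc.ClassifierConfig(k=3, min_kmer_count=1, canonical=False)

    def two_label_index(self):
        return armc.build_index({"2HS": "A" * 21, "2HL": "C" * 21}, self.cfg3)

    def test_confidence_exactly_at_threshold_is_unassigned(self):
        """h = {2HS: 30, 2HL: 10} -> confidence 0.75, not > 0.75 -> UNASSIGNED."""
        index = self.two_label_index()
        bac = BacAssembly("b1", {"n0": "A" * 32, "n1": "C" * 12})
        a = armc.classify(index, bac, self.cfg3)
        assert a.hits == {"2HS": 30, "2HL": 10}
        assert a.confidence == pytest.approx(0.75)
        assert a.label == armc.UNASSIGNED

    def test_just_above_threshold_is_assigned(self):
        index = self.two_label_index()
        bac = BacAssembly("b1", {"n0": "A" * 33, "n1": "C" * 12})  # 31 vs 10
        a = armc.classify(index, bac, self.cfg3)
        assert a.label == "2HS"
        assert a.confidence > 0.75

    def test_no_indexed_kmers_gives_unassigned_confidence_zero(self):
        index = self.two_label_index()
        a = armc.classify(index, BacAssembly("b", {"n0": "G" * 30}), self.cfg3)
        assert a.label == armc.UNASSIGNED and a.confidence == 0.0

    def test_tie_for_top_label_is_unassigned(self):
        index = self.two_label_index()
        a = armc.classify(index, BacAssembly("b", {"n0": "A" * 12, "n1": "C" * 12}), self.cfg3)
        assert a.label == armc.UNASSIGNED

    def test_verbatim_target_slice_classifies_with_confidence_one(self, clean_genome):
        cfg = armc.ClassifierConfig(k=19, min_kmer_count=1)
        index = armc.build_index(clean_genome.arm_targets, cfg)
        s_len, overlap = clean_genome.arm_boundaries["3H"]
        # unique region of 3HL: beyond the centromeric overlap
        seq = clean_genome.sequences["3H"][s_len + 1_000 : s_len + 11_000]
        a = armc.classify(index, BacAssembly("b", {"n0": seq}), cfg)
        assert a.label == "3HL"
        assert a.confidence == 1.0

    def test_k_mismatch_raises(self):
        index = self.two_label_index()
        with pytest.raises(DataError, match="k mismatch"):
            armc.classify(index, BacAssembly("b", {"n": "AAAA"}),
                          armc.ClassifierConfig(k=5, canonical=False))

    def test_node_order_invariance(self, clean_genome):
        cfg = armc.ClassifierConfig(k=19, min_kmer_count=1)
        index = armc.build_index(clean_genome.arm_targets, cfg)
        seq = clean_genome.sequences["2H"][10_000:30_000]
        nodes = {f"n{i}": seq[i * 4_000 : (i + 1) * 4_000] for i in range(5)}
        a1 = armc.classify(index, BacAssembly("b", nodes), cfg)
        shuffled = dict(reversed(list(nodes.items())))
        a2 = armc.classify(index, BacAssembly("b", shuffled), cfg)
        assert (a1.label, a1.confidence, a1.hits) == (a2.label, a2.confidence, a2.hits)

    def test_appending_label_kmers_is_monotone(self):
        index = self.two_label_index()
        base = BacAssembly("b", {"n0": "A" * 30})
        more = BacAssembly("b", {"n0": "A" * 30, "n1": "A" * 30})
        h_base = armc.classify(index, base, self.cfg3).hits.get("2HS", 0)
        h_more = armc.classify(index, more, self.cfg3).hits.get("2HS", 0)
        assert h_more >= h_base


def test_classify_library_counts_sum_to_size(clean_genome):
    from bacatlas.synthetic import simulate_bac_library

    cfg = armc.ClassifierConfig(k=19, min_kmer_count=1)
    index = armc.build_index(clean_genome.arm_targets, cfg)
    lib = simulate_bac_library(clean_genome, n_clones=40, insert_mean=30_000,
                               insert_sd=3_000, node_split=3, seed=9)
    assignments, summary = armc.classify_library(index, lib, cfg)
    assert sum(summary["per_label"].values()) == len(lib) == summary["n_bacs"]
    truth = lib.truth.set_index("bac_id")["true_label"]
    assigned = [a for a in assignments if a.label != armc.UNASSIGNED]
    correct = sum(a.label == truth[a.bac_id] for a in assigned)
    assert len(assigned) >= 0.9 * len(lib)
    assert correct / len(assigned) >= 0.95


def test_classify_empty_library(clean_genome):
    cfg = armc.ClassifierConfig(k=19, min_kmer_count=1)
    index = armc.build_index(
        {"2HS": clean_genome.arm_targets["2HS"][:5_000], "2HL": clean_genome.arm_targets["2HL"][:5_000]},
        cfg,
    )
    assignments, summary = armc.classify_library(index, [], cfg)
    assert assignments == [] and summary["assignment_rate_pct"] == 0.0
    assert summary["n_bacs"] == 0
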