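import hashlib

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldassign import model_io, synthetic
from foldassign.model_io import (DomainHit, FragmentSet, ModelParseError,
                                 StructureModel, load_hits, parse_model,
                                 parse_segments, sequence_md5, write_domain,
                                 write_model)
from foldassign.resolution import DomainRegion


class TestSequenceMd5:
    def test_known_digest(self):
        # MD5 of the single byte "A" (independent oracle: hashlib direct)
        assert sequence_md5("A") == "7fc56270e7a70fa81a5935b72eacbe29"
        assert sequence_md5("ACDEFG") == hashlib.md5(b"ACDEFG").hexdigest()

    def test_deterministic_and_discriminating(self):
        assert sequence_md5("ALA" * 20) == sequence_md5("ALA" * 20)
        assert sequence_md5("AAAA") != sequence_md5("AAAC")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sequence_md5("")

    def test_no_collisions_on_random_battery(self):
        rng = np.random.default_rng(0)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        seqs = {"".join(rng.choice(alphabet, size=rng.integers(10, 60)))
                for _ in range(10_000)}
        digests = {sequence_md5(s) for s in seqs}
        assert len(digests) == len(seqs)


class TestSegments:
    @pytest.mark.parametrize("text,expected,nres", [
        ("12-110", [(12, 110)], 99),
        ("5-60,80-140", [(5, 60), (80, 140)], 117),
    ])
    def test_parse(self, text, expected, nres):
        segs = parse_segments(text)
        assert segs == expected
        assert sum(b - a + 1 for a, b in segs) == nres

    @pytest.mark.parametrize("bad", ["60-5", "10-20,15-30", "banana", "5"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_segments(bad)


class TestLoadHits:
    def test_table_roundtrip(self, tmp_path):
        hits = [
            DomainHit("P1", "CATH-HMM", "3.40.50.620", [(12, 110)], 250.0),
            DomainHit("P1", "Pfam", "PF00042", [(5, 60), (80, 140)], 99.5),
            DomainHit("P2", "NewFam", "", [(1, 80)], 40.0),
        ]
        path = tmp_path / "hits.tsv"
        model_io.write_hits(hits, path)
        loaded = load_hits(path)
        assert loaded == hits
        assert loaded[1].n_residues == 117

    def test_bad_row_reported_with_number(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("P1\t1.10.8.10\t50\t10-60\nP2\tPF1\t20\t60-5\n")
        with pytest.raises(ValueError, match="row 2"):
            load_hits(path)

    def test_source_inferred_from_family_shape(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("P1\t1.10.8.10\t50\t10-60\n"
                        "P1\tPF00001\t50\t70-130\n"
                        "P1\t-\t50\t140-200\n")
        sources = [h.source for h in load_hits(path)]
        assert sources == ["CATH-HMM", "Pfam", "NewFam"]


class TestParseModel:
    def test_plddt_from_b_factor(self, tmp_path, helix20):
        path = write_model(synthetic.inject_plddt(helix20, 88.0),
                           tmp_path / "m.pdb")
        model = parse_model(path, protein_id="helix")
        assert model.n_residues == 20
        assert np.allclose(model.plddt, 88.0)

    def test_non_atom_records_ignored(self, tmp_path, helix20):
        path = write_model(helix20, tmp_path / "m.pdb")
        lines = path.read_text().splitlines()
        noisy = []
        for i, line in enumerate(lines):
            noisy.append(line)
            if i % 7 == 0:
                noisy.insert(-1, "HETATM    1  O   HOH A 999     "
                                 "  0.000   0.000   0.000  1.00  0.00")
                noisy.append("TER")
        noisy_path = tmp_path / "noisy.pdb"
        noisy_path.write_text("\n".join(noisy) + "\n")
        assert parse_model(noisy_path, "helix") == parse_model(path, "helix")

    def test_roundtrip_preserves_fields(self, tmp_path, compact_bundle):
        rng = np.random.default_rng(3)
        profile = np.round(rng.uniform(40, 100, compact_bundle.n_residues), 2)
        model = synthetic.inject_plddt(compact_bundle, profile)
        path = write_model(model, tmp_path / "b.pdb")
        assert parse_model(path, protein_id="bundle") == model

    def test_multichain_rejected(self, tmp_path, helix20):
        path = write_model(helix20, tmp_path / "m.pdb")
        text = path.read_text()
        second = text.replace(" A ", " B ")
        (tmp_path / "two.pdb").write_text(
            text.replace("END\n", "") + second)
        with pytest.raises(ModelParseError, match="chain"):
            parse_model(tmp_path / "two.pdb")

    def test_missing_ca_named_in_error(self, tmp_path, helix20):
        path = write_model(helix20, tmp_path / "m.pdb")
        kept = [l for l in path.read_text().splitlines()
                if not (l.startswith("ATOM") and l[12:16].strip() == "CA"
                        and l[22:26].strip() == "7")]
        (tmp_path / "noca.pdb").write_text("\n".join(kept) + "\n")
        with pytest.raises(ModelParseError, match="7"):
            parse_model(tmp_path / "noca.pdb")

    def test_altloc_rejected(self, tmp_path, helix20):
        path = write_model(helix20, tmp_path / "m.pdb")
        lines = path.read_text().splitlines()
        out = []
        for line in lines:
            if line.startswith("ATOM") and " CA " in line and out.count:
                line = line[:16] + "A" + line[17:]
            out.append(line)
        (tmp_path / "alt.pdb").write_text("\n".join(out) + "\n")
        with pytest.raises(ModelParseError, match="[Aa]lternate"):
            parse_model(tmp_path / "alt.pdb")


class TestWriteDomain:
    def test_chop_preserves_numbering(self, tmp_path, compact_bundle):
        region = DomainRegion("bundle", [(10, 20)])
        path = write_domain(compact_bundle, region,
                            path=tmp_path / "dom.pdb")
        sub = parse_model(path, protein_id="bundle")
        assert sub.seq_indices == list(range(10, 21))
        assert sub == compact_bundle.subset(range(10, 21))

    def test_metadata_headers(self, tmp_path, compact_bundle):
        region = DomainRegion("bundle", [(1, 45)], source="CATH-HMM",
                              candidate_superfamily="1.10.8.10")
        path = write_domain(compact_bundle, region,
                            path=tmp_path / "dom.pdb",
                            metadata={"md5": "deadbeef"})
        text = path.read_text()
        sub = compact_bundle.subset(range(1, 46))
        assert f"DOMAIN_MD5 {sub.sequence_md5}" in text
        assert "MD5 deadbeef" in text
        assert "FAMILY 1.10.8.10" in text
        assert "SOURCE_FILE bundle_F1" in text

    def test_missing_residues_listed(self, tmp_path, compact_bundle):
        region = DomainRegion("bundle", [(60, 70)])
        with pytest.raises(KeyError, match="6[3-9]"):
            write_domain(compact_bundle, region, path=tmp_path / "x.pdb")

    def test_filename_stem_convention(self):
        stem = model_io.region_filename_stem("P12345", [(10, 110), (150, 200)])
        assert stem == "P12345_10-110_150-200"


class TestFragmentSet:
    def test_short_protein_single_fragment(self):
        fs = FragmentSet.for_length("P", 900)
        assert fs.fragments == [(1, 1, 900)]

    def test_sliding_window_coverage(self):
        fs = FragmentSet.for_length("P", 2700)
        starts = [f[1] for f in fs.fragments]
        assert starts[0] == 1
        assert all(b - a == 200 for a, b in zip(starts, starts[1:-1]))
        assert fs.fragments[-1][2] == 2700
        covered = set()
        for _, first, last in fs.fragments:
            assert last - first + 1 == 1400
            covered.update(range(first, last + 1))
        assert covered == set(range(1, 2701))


@settings(max_examples=200, derandomize=True)
@given(st.lists(st.tuples(st.integers(1, 500), st.integers(1, 500)),
                min_size=1, max_size=5))
def test_segment_validation_property(pairs):
    """Segments parse back from their formatted form iff they are valid
    (sorted, disjoint, start <= stop)."""
    segs = [(min(a, b), max(a, b)) for a, b in pairs]
    segs.sort()
    valid = all(b1 < a2 for (_, b1), (a2, _) in zip(segs, segs[1:]))
    text = model_io.format_segments(segs)
    if valid:
        assert parse_segments(text) == segs
    else:
        with pytest.raises(ValueError):
            parse_segments(text)
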