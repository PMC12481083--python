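import numpy as np
import pandas as pd
import pytest

from panelprs.genotypes import DosageMatrix, read_depths, read_dosages, write_vcf
from panelprs.model import VariantDefinition

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n##contig=<ID=2>\n"
)


def _vcf(tmp_path, body_rows, samples=("S1", "S2", "S3")):
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines = [VCF_HEADER + "\t".join(cols + list(samples))]
    lines += ["\t".join(str(f) for f in row) for row in body_rows]
    path = tmp_path / "calls.vcf"
    path.write_text("\n".join(lines) + "\n")
    return path


def test_effect_allele_orientation(tmp_path):
    path = _vcf(
        tmp_path,
        [("1", 100, ".", "A", "C", ".", ".", ".", "GT", "0/1", "0/0", "1/1")],
    )
    alt_effect = [VariantDefinition("1:100:A:C", "1", 100, "A", "C", "C", 0.1)]
    ref_effect = [VariantDefinition("1:100:A:C", "1", 100, "A", "C", "A", 0.1)]
    d_alt = read_dosages(path, alt_effect).data["1:100:A:C"]
    d_ref = read_dosages(path, ref_effect).data["1:100:A:C"]
    assert list(d_alt) == [1.0, 0.0, 2.0]
    assert list(d_ref) == [1.0, 2.0, 0.0]
    # complementary orientations always sum to 2 for called diploid genotypes
    assert list(d_alt + d_ref) == [2.0, 2.0, 2.0]


def test_uncalled_and_half_called_genotypes_are_missing(tmp_path):
    path = _vcf(
        tmp_path,
        [("1", 200, ".", "G", "T", ".", ".", ".", "GT", "0/1", "./1", "./.")],
    )
    variants = [VariantDefinition("1:200:G:T", "1", 200, "G", "T", "T", 0.1)]
    col = read_dosages(path, variants).data["1:200:G:T"]
    assert col["S1"] == 1.0
    assert np.isnan(col["S2"]) and np.isnan(col["S3"])


def test_multiallelic_decomposition_and_mismatches(tmp_path):
    path = _vcf(
        tmp_path,
        [("2", 300, ".", "T", "A,G", ".", ".", ".", "GT", "0/1", "0/2", "1/2")],
    )
    v_a = [VariantDefinition("2:300:T:A", "2", 300, "T", "A", "A", 0.1)]
    v_g = [VariantDefinition("2:300:T:G", "2", 300, "T", "G", "G", 0.1)]
    col_a = read_dosages(path, v_a).data["2:300:T:A"]
    col_g = read_dosages(path, v_g).data["2:300:T:G"]
    assert col_a["S1"] == 1.0  # 0/1 carries one A
    assert np.isnan(col_a["S2"]) and np.isnan(col_a["S3"])  # carry the other alt
    assert col_g["S2"] == 1.0
    assert np.isnan(col_g["S1"]) and np.isnan(col_g["S3"])


def test_variant_absent_from_vcf_is_missing(tmp_path):
    path = _vcf(
        tmp_path,
        [("1", 100, ".", "A", "C", ".", ".", ".", "GT", "0/0", "0/0", "0/0")],
    )
    variants = [
        VariantDefinition("1:100:A:C", "1", 100, "A", "C", "C", 0.1),
        VariantDefinition("1:999:A:G", "1", 999, "A", "G", "G", 0.1),
    ]
    mat = read_dosages(path, variants)
    assert mat.data["1:999:A:G"].isna().all()


def test_chr_prefix_and_padded_indels_match(tmp_path):
    # VCF spells the deletion with an extra shared suffix base and a chr prefix;
    # the model uses the minimal left-aligned form
    path = _vcf(
        tmp_path,
        [("2", 400, ".", "TAC", "TC", ".", ".", ".", "GT", "0/1", "1/1", "0/0")],
    )
    variants = [VariantDefinition("2:400:TA:T", "chr2", 400, "TA", "T", "T", 0.1)]
    col = read_dosages(path, variants).data["2:400:TA:T"]
    assert list(col) == [1.0, 2.0, 0.0]


def _hand_parse_vcf(path, variants):
    """Independent oracle: line-by-line text walk, no pysam."""
    by_key = {}
    for v in variants:
        by_key[(v.chromosome, v.position, v.ref_allele, v.alt_allele)] = v
    samples, table = [], {}
    for line in path.read_text().splitlines():
        if line.startswith("##"):
            continue
        fields = line.split("\t")
        if line.startswith("#CHROM"):
            samples = fields[9:]
            continue
        chrom, pos, _, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
        v = by_key.get((chrom, pos, ref, alt))
        if v is None:
            continue
        for sample, cell in zip(samples, fields[9:]):
            gt = cell.split(":")[0].replace("|", "/").split("/")
            if "." in gt or len(gt) != 2:
                continue
            alt_count = sum(1 for a in gt if a == "1")
            table[(sample, v.variant_id)] = (
                alt_count if v.effect_allele == v.alt_allele else 2 - alt_count
            )
    return table


def test_read_dosages_matches_hand_parse_oracle(tmp_path, rng):
    variants = []
    for i in range(20):
        ref, alt = ("A", "G") if i % 2 else ("C", "T")
        effect = alt if i % 3 else ref
        variants.append(
            VariantDefinition(f"1:{1000 + i}:{ref}:{alt}", "1", 1000 + i, ref, alt, effect, 0.1)
        )
    samples = [f"S{j}" for j in range(10)]
    data = pd.DataFrame(
        rng.integers(0, 3, size=(10, 20)).astype(float),
        index=samples,
        columns=[v.variant_id for v in variants],
    )
    path = tmp_path / "cohort.vcf"
    write_vcf(path, variants, DosageMatrix(data))
    mat = read_dosages(path, variants)
    oracle = _hand_parse_vcf(path, variants)
    assert len(oracle) == 200
    for (sample, vid), expected in oracle.items():
        assert mat.data.at[sample, vid] == expected


def test_sample_column_order_does_not_change_dosages(tmp_path):
    row = ("1", 100, ".", "A", "C", ".", ".", ".", "GT")
    variants = [VariantDefinition("1:100:A:C", "1", 100, "A", "C", "C", 0.1)]
    dir_a, dir_b = tmp_path / "a", tmp_path / "b"
    dir_a.mkdir()
    dir_b.mkdir()
    p1 = _vcf(dir_a, [row + ("0/1", "1/1", "0/0")], samples=("S1", "S2", "S3"))
    m1 = read_dosages(p1, variants)
    p2 = _vcf(dir_b, [row + ("0/0", "0/1", "1/1")], samples=("S3", "S1", "S2"))
    m2 = read_dosages(p2, variants)
    pd.testing.assert_frame_equal(m1.data, m2.data.loc[m1.data.index])


def test_dosage_matrix_rejects_out_of_range_values():
    with pytest.raises(ValueError, match="0, 1 or 2"):
        DosageMatrix(pd.DataFrame({"v": [3.0]}, index=["S1"]))


def test_read_depths_toy_table_and_absent_rows(tmp_path, toy_model):
    path = tmp_path / "depths.tsv"
    path.write_text(
        "sample\tchrom\tpos\tdepth\n"
        "S1\t1\t100\t559\n"
        "S1\tchr1\t200\t12\n"
        "S2\t1\t100\t0\n"
    )
    table = read_depths(path, toy_model, sample_ids=["S1", "S2"])
    assert table.data.at["S1", "1:100:A:C"] == 559
    assert table.data.at["S1", "1:200:G:T"] == 12
    assert table.data.at["S2", "1:100:A:C"] == 0
    # rows absent from the file are depth 0
    assert table.data.at["S2", "2:400:TA:T"] == 0


def test_read_depths_empty_file_gives_all_zero(tmp_path, toy_model):
    path = tmp_path / "depths.tsv"
    path.write_text("sample\tchrom\tpos\tdepth\n")
    table = read_depths(path, toy_model, sample_ids=["S1"])
    assert (table.data.to_numpy() == 0).all()


def test_read_depths_rejects_negative(tmp_path, toy_model):
    path = tmp_path / "depths.tsv"
    path.write_text("sample\tchrom\tpos\tdepth\nS1\t1\t100\t-3\n")
    with pytest.raises(ValueError, match="negative"):
        read_depths(path, toy_model)


def test_vcf_round_trip_on_simulated_cohort(tmp_path, small_study):
    cohort = small_study.cohort
    path = tmp_path / "truth.vcf"
    write_vcf(path, cohort.panel_variants, cohort.truth)
    back = read_dosages(path, cohort.panel_variants)
    pd.testing.assert_frame_equal(
        back.data.loc[cohort.truth.sample_ids, cohort.truth.variant_ids],
        cohort.truth.data,
    )
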