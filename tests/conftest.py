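import textwrap

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def write_vcf(tmp_path):
    """Write a small plain-text VCF from (chrom, pos, id, ref, alt, gts) rows.

    ``gts`` is a list of genotype strings ("0/0", "0|1", "./.", ...), one
    per sample in ``samples`` order.
    """

    def _write(samples, rows, name="test.vcf"):
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            chroms = sorted({r[0] for r in rows})
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write(
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples) + "\n"
            )
            for chrom, pos, vid, ref, alt, gts in rows:
                fh.write(
                    f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts) + "\n"
                )
        return path

    return _write


@pytest.fixture
def write_panel(tmp_path):
    def _write(pairs, name="panel.txt", header=True):
        path = tmp_path / name
        with open(path, "w") as fh:
            if header:
                fh.write("sample\tpop\tsuper_pop\n")
            for sample, pop in pairs:
                fh.write(f"{sample}\t{pop}\t{pop}\n")
        return path

    return _write


@pytest.fixture
def write_manifest(tmp_path):
    def _write(rows, name="manifest.csv"):
        path = tmp_path / name
        lines = ["IlmnID,CHR,MAPINFO,Strand,Infinium_Design_Type"]
        lines += [",".join(str(x) for x in r) for r in rows]
        path.write_text(textwrap.dedent("\n".join(lines)) + "\n")
        return path

    return _write
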