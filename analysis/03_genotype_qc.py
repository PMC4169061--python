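"""Apply the four-step genotype QC and write the analysis-ready call set.

Filter order: per-call quality (any call < 0.7 removes the SNP),
completeness (any missing call removes it), MAF < 0.1, exact
Hardy-Weinberg at alpha = 0.001. Each SNP is attributed to the first
filter that removes it.
"""

import json

from _lib import load_config

from micronet import io as mio
from micronet.qc import run_qc

C = load_config()


def main() -> None:
    calls = mio.read_genotypes(C.INPUTS / "genotypes.tsv")
    quality = mio.read_quality(C.INPUTS / "quality.tsv")
    kept, report = run_qc(calls, quality)
    kept.to_csv(C.RESULTS / "genotypes_qc.tsv", sep="\t")
    (C.RESULTS / "qc_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    report.snp_stats.round(6).to_csv(C.RESULTS / "qc_snp_stats.tsv", sep="\t")
    print(f"input SNPs: {report.n_input}")
    for name, n in report.removed.items():
        print(f"  removed by {name}: {n}")
    print(f"surviving: {report.n_surviving}")


if __name__ == "__main__":
    main()
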