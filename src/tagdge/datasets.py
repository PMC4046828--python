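"""Curated reference data from a published pear fruit tag-DGE experiment.

Two small tables from a deep five-stage sand pear (Pyrus) fruit-development
digital gene expression study are bundled for validation and as worked-
example inputs:

* :func:`library_summary_counts` — the per-library tag accounting of the
  five stage libraries (FS1-FS5, 25-145 days post anthesis): raw, clean,
  gene-mapping, unambiguous and unknown tag totals plus gene counts, against
  a reference of 90,227 unigenes.  The published percentage rows of that
  report can be recomputed from these counts with :func:`tagdge.qc.percent`;
  two published cells are inconsistent with the published counts themselves
  (FS2 clean/raw prints 96.40 where the counts give 97.17, and FS3
  tags-mapping prints 82.18 where the counts give 82.16).  The FS1 column
  recomputes exactly.

* :func:`ripening_profiles` — 39 unigene TPM profiles across the five
  stages with their published trend-group labels (up-regulated,
  down-regulated, low-high-low, constitutive).  They serve as a reference
  panel for the rule-based trend classifier.  A few profiles were printed
  as run-together digit strings in the source and were re-tokenised here;
  the plasma-membrane ATPase row spans a 14-fold range yet is labelled
  constitutive and is known not to be reproducible by any amplitude rule.
"""

from __future__ import annotations

import io

import pandas as pd

#: unigenes in the study's transcriptome reference
REFERENCE_GENES = 90_227

_LIBRARY_SUMMARY = """\
statistic\tFS1\tFS2\tFS3\tFS4\tFS5
raw_total\t5942273\t5765350\t5930561\t6154708\t6144427
raw_distinct\t275061\t279671\t273457\t278272\t284436
clean_total\t5779213\t5602344\t5771830\t5987439\t5968618
clean_distinct\t127209\t130176\t128372\t125656\t122997
mapped_copies\t4601197\t4514247\t4742242\t4916898\t4676676
mapped_distinct\t73993\t76128\t77039\t74448\t68916
tag_mapped_genes\t34781\t35530\t36335\t35415\t32705
unambiguous_copies\t3875820\t3766999\t3956567\t4137841\t3856928
unambiguous_distinct\t61872\t63617\t64242\t61873\t56894
unambiguous_genes\t26836\t27541\t28175\t27331\t24975
unknown_copies\t1178016\t1088097\t1028588\t1070541\t1291942
unknown_distinct\t53216\t54048\t51333\t51208\t54081
"""

#: published percentage rows of the same report, to two decimals
_LIBRARY_PERCENTAGES = """\
statistic\tFS1\tFS2\tFS3\tFS4\tFS5
pct_clean_of_raw\t97.26\t96.40\t97.32\t97.28\t97.14
pct_mapped_copies\t79.62\t80.58\t82.18\t82.12\t78.35
pct_mapped_distinct\t58.17\t58.48\t60.01\t59.25\t56.03
pct_tag_mapped_genes\t38.55\t39.38\t40.27\t39.25\t36.25
pct_unambiguous_copies\t67.06\t67.24\t68.55\t69.11\t64.62
pct_unambiguous_distinct\t48.64\t48.87\t50.04\t49.24\t46.26
pct_unambiguous_genes\t29.74\t30.52\t31.23\t30.29\t27.68
pct_unknown_copies\t20.38\t19.42\t17.82\t17.88\t21.65
pct_unknown_distinct\t41.83\t41.52\t39.99\t40.75\t43.97
"""

_PROFILES = """\
gene_id\tannotation\tfs1\tfs2\tfs3\tfs4\tfs5\tgroup
Unigene86203_PB_AHAU\tSucrose phosphate synthase\t0.35\t0.54\t1.39\t1.84\t0.84\tI_up
Unigene51453_PB_AHAU\tStarch synthase\t6.75\t11.07\t21.3\t19.69\t30.83\tI_up
Unigene28216_PB_AHAU\tAlkaline invertase\t66.27\t107.11\t49.35\t209.27\t190.33\tI_up
Unigene31510_PB_AHAU\tPhosphofructokinase\t1.21\t0.89\t15.25\t21.55\t25.8\tI_up
Unigene79028_PB_AHAU\tMaltose transporter\t30.11\t34.45\t35.17\t72.65\t123.31\tI_up
Unigene7706_PB_AHAU\tAldehyde dehydrogenase\t48.28\t59.44\t87.67\t93.03\t102.54\tI_up
Unigene11393_PB_AHAU\tExpansin\t21.63\t20.35\t39.33\t74.99\t148.11\tI_up
Unigene84426_PB_AHAU\tACC oxidase\t8.82\t13.57\t13.69\t6.68\t159\tI_up
Unigene41650_PB_AHAU\t4-Hydroxyphenylpyruvate dioxygenase\t0\t0.54\t3.47\t4.01\t5.36\tI_up
Unigene49425_PB_AHAU\tLeucoanthocyanidin dioxygenase\t1.73\t11.07\t13.34\t49.77\t36.19\tI_up
Unigene78545_PB_AHAU\tAuxin influx transport protein\t130.12\t120.31\t136.7\t65.97\t32.84\tII_down
Unigene28595_PB_AHAU\tSucrose synthase\t1120.57\t775.21\t201.84\t18.2\t5.7\tII_down
Unigene2239_PB_AHAU\tPyrophosphate-dependent phosphofructo-1-kinase\t28.38\t16.42\t2.08\t3.01\t1.01\tII_down
Unigene82187_PB_AHAU\tAlcohol acyl-transferase\t179.78\t215.27\t80.22\t12.86\t19.43\tII_down
Unigene21328_PB_AHAU\tAlcohol acyl-transferase\t185.49\t154.04\t102.91\t14.53\t9.55\tII_down
Unigene41185_PB_AHAU\tAlcohol acyl-transferase\t958.95\t738.98\t286.74\t201.42\t84.78\tII_down
Unigene24664_PB_AHAU\tFlavonoid 3-hydroxylase\t114.55\t62.47\t0\t3.67\t0.34\tII_down
Unigene89425_PB_AHAU\tCOL domain class transcription factor\t100.88\t80.86\t13.34\t10.52\t4.36\tII_down
Unigene40707_PB_AHAU\tArogenate/prephenate dehydratase\t309.04\t207.23\t45.74\t17.04\t9.21\tII_down
Unigene42300_PB_AHAU\tUDPG flavonoid 7-O-glucosyltransferase\t125.62\t192.42\t72.25\t34.07\t67.52\tII_down
Unigene28017_PB_AHAU\tNAD-dependent sorbitol dehydrogenase\t9.52\t6.96\t21.66\t11.69\t4.02\tIII_low_high_low
Unigene48458_PB_AHAU\tNAD-dependent sorbitol dehydrogenase\t65.58\t60.15\t208.43\t94.87\t28.15\tIII_low_high_low
Unigene40996_PB_AHAU\tp-Hydroxyphenylpyruvate dioxygenase\t0.52\t1.25\t12.13\t6.68\t8.88\tIII_low_high_low
Unigene36705_PB_AHAU\tCytochrome P450\t36.68\t39.98\t208.77\t167.35\t69.7\tIII_low_high_low
Unigene1335_PB_AHAU\tCytochrome P450\t12.46\t8.21\t77.96\t21.38\t11.9\tIII_low_high_low
Unigene15706_PB_AHAU\tSalt-tolerance protein\t14.36\t16.78\t83.86\t18.2\t13.57\tIII_low_high_low
Unigene6651_PB_AHAU\tDELLA protein\t44.99\t40.7\t80.74\t32.45\t1.44\tIII_low_high_low
Unigene29424_PB_AHAU\tPolyphenol oxidase\t33.57\t28.02\t79.52\t40.92\t14.07\tIII_low_high_low
Unigene2416_PB_AHAU\tGibberellin oxidase\t0.35\t1.61\t77.96\t17.7\t0\tIII_low_high_low
Unigene1535_PB_AHAU\tS6 ribosomal protein\t650.26\t506.57\t717.1\t432.91\t403.28\tIV_constitutive
Unigene42402_PB_AHAU\tStructural molecule activity\t505.09\t381.09\t387.23\t437.58\t380.99\tIV_constitutive
Unigene41042_PB_AHAU\tDEAD-box RNA helicase-like protein\t481.38\t399.83\t458.09\t641.68\t533.46\tIV_constitutive
Unigene41056_PB_AHAU\tLarge ribosomal subunit\t333.09\t256.14\t291.59\t243.18\t225.51\tIV_constitutive
Unigene40598_PB_AHAU\tPlasma membrane ATPase\t29.93\t22.13\t20.62\t50.11\t3.57\tIV_constitutive
Unigene41711_PB_AHAU\tPlasma membrane intrinsic protein\t19.38\t28.92\t41.23\t23.88\t21.11\tIV_constitutive
Unigene8634_PB_AHAU\tPlasma intrinsic protein\t1121.95\t866.6\t964.51\t974.21\t799.18\tIV_constitutive
Unigene13819_PB_AHAU\tBHLH domain class transcription factor\t212.49\t243.11\t169.79\t168.85\t206.92\tIV_constitutive
Unigene3327_PB_AHAU\t60S ribosomal protein L35a\t180.65\t182.6\t166.5\t154.99\t138.73\tIV_constitutive
Unigene40848_PB_AHAU\tRibosomal protein S21e\t173.03\t218.12\t188.33\t170.36\t182.62\tIV_constitutive
"""


def library_summary_counts() -> pd.DataFrame:
    """Per-library tag-accounting counts (statistics x libraries FS1-FS5)."""
    return pd.read_csv(io.StringIO(_LIBRARY_SUMMARY), sep="\t", index_col="statistic")


def library_summary_percentages() -> pd.DataFrame:
    """The published percentage rows of the same report (two decimals)."""
    return pd.read_csv(io.StringIO(_LIBRARY_PERCENTAGES), sep="\t", index_col="statistic")


def ripening_profiles() -> pd.DataFrame:
    """39 five-stage TPM profiles with published trend-group labels."""
    return pd.read_csv(io.StringIO(_PROFILES), sep="\t")
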