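"""Bundled reference tables from a published accelerated-iTBS cohort.

Small published summary tables of an open-label 5-day accelerated iTBS
(SAINT-protocol) cohort of depressed patients with suicidal ideation
(n = 32 treated, 26 with analyzable imaging). They serve as worked-example
inputs and validation fixtures: per-patient stimulation-target coordinates
with outcome reductions, and cohort-level scale summaries.

Values are stored exactly as printed, including two known printing
inconsistencies in the source tables (the 4-week suicidal-ideation
response rate appears both as 90.63% and 93.33%, and the immediate HAMD-17
mean reduction is printed as 66.39% while the rounded summary means give
66.46%); see the package methods note.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["stimulation_targets", "clinical_summary"]

# Per-patient stimulation-target MNI coordinates (mm), coil-target depth,
# resting motor threshold, and fractional score reductions immediately
# after the 5-day course.
_TARGETS_TSV = """\
patient	x	y	z	depth_mm	rmt_pct	bsi_cv_reduction	hamd17_reduction	madrs_reduction
1	-26	45	28	20.49	65	0.22	0.64	0.54
2	-26	48	25	22.76	55	1.00	0.76	0.68
3	-29	49	32	24.86	25	1.00	0.59	0.62
4	-36	44	34	17.48	70	0.45	0.68	0.63
5	-27	50	23	22.34	30	1.00	0.79	0.78
6	-25	53	20	19.11	65	1.00	0.84	0.73
7	-40	52.5	4	21.53	45	0.72	0.74	0.60
8	-42	52	13	25.24	55	0.90	0.89	0.75
9	-32	21	40	21.15	55	0.50	0.48	0.46
10	-41	53	3	29.46	60	0.84	0.68	0.66
11	-26	48	27	20.67	60	0.83	0.83	0.83
12	-31	50	33	24.75	60	0.43	0.78	0.64
13	-40	50	1	21.92	70	0.36	0.81	0.84
14	-26	55	28	24.63	70	0.56	0.89	0.69
15	-30	48	34	17.79	35	0.47	0.86	0.78
16	-29	45	32	17.93	30	0.88	0.66	0.83
17	-41	52	8	17.91	60	0.44	0.59	0.26
18	-26	44	30	22.35	45	0.88	0.71	0.53
19	-30	48	35	23.17	70	1.00	0.77	0.83
20	-28	52	25	20.38	45	0.60	0.41	0.33
21	-28	48	32	20.45	70	0.33	0.69	0.59
22	-40	53	6	25.88	70	0.39	0.25	0.20
23	-30	38	30	17.59	75	0.44	0.75	0.50
24	-27	54	24	20.75	55	0.52	0.46	0.51
25	-36	33	37	16.78	60	0.33	0.59	0.58
26	-39	53	-1	17.95	45	0.28	0.34	0.31
"""

# Cohort scale summaries (n = 32): means/SDs per timepoint and, where
# defined, response/remission counts with printed percentages.
_SUMMARY_TSV = """\
scale	timepoint	mean	sd	response_n	response_pct	remission_n	remission_pct
BSI-CV	baseline	17.63	7.06
BSI-CV	post	6.13	5.98	21	65.63	18	56.25
BSI-CV	week2	5.81	6.01	25	78.13	19	59.38
BSI-CV	week4	3.39	4.53	29	90.63	24	75.00
HAMD-17	baseline	27.91	4.31
HAMD-17	post	9.36	5.43	26	81.25	17	53.13
HAMD-17	week2	7.84	4.57	29	90.63	18	56.25
HAMD-17	week4	5.72	4.24	30	93.75	26	81.25
MADRS	baseline	36.69	4.49
MADRS	post	15.06	7.24	25	78.13	9	28.13
MADRS	week2	11.28	5.67	29	90.63	18	56.25
MADRS	week4	8.45	5.17	31	96.88	25	78.13
BDI	baseline	35.75	9.17
BDI	post	21.41	10.92	13	40.63	8	25.00
BDI	week2	19.44	10.33	20	62.50	10	31.25
BDI	week4	14.33	7.75	23	71.88	15	46.88
HAMD-6	baseline	13.63	2.17
HAMD-6	post	4.41	2.66	26	81.25	19	59.38
PDQ-D	baseline	42.13	15.65
PDQ-D	post	30.22	17.27
DST	baseline	13.50	2.31
DST	post	14.88	2.54
DSST	baseline	55.19	11.60
DSST	post	63.63	11.89
"""

# Strings printed elsewhere in the source report that disagree with the
# summary table; preserved verbatim, never used as computed targets.
PRINTED_DISCREPANCIES = {
    "week4_si_response_pct_alt": "93.33",
    "post_hamd17_mean_reduction_pct": "66.39",
}


def stimulation_targets() -> pd.DataFrame:
    """Per-patient targets and immediate fractional outcome reductions (n=26)."""
    return pd.read_csv(io.StringIO(_TARGETS_TSV), sep="\t")


def clinical_summary() -> pd.DataFrame:
    """Cohort-level scale summaries by timepoint (n=32 treated patients)."""
    return pd.read_csv(io.StringIO(_SUMMARY_TSV), sep="\t")
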