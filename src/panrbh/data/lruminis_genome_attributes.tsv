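strain	gut_source	size_mbp	gc_percent	orf_count	protein_count
GRL1172	porcine	2.02	43.3	2165	2105
DPC6830	porcine	2.04	43.3	1975	1825
DPC6832	equine	1.94	43.1	1897	1755
ATCC25644	human	2.11	43.7	2072	1968
SPM0211	human	2.17	43.7	2127	2013
S23	human	1.91	43.7	1845	1686
ATCC27782	bovine	2.07	43.5	2035	1836
PEL65	bovine	2.06	43.4	2194	2104
PEL66	bovine	2.02	43.4	2170	2086
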