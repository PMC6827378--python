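mutation	doubling_time_min	heat_shock_fold
reference	65.5	1.0
A20bG	67.4	1.6
G9A	68.3	1.2
U44G	71.6	2.4
C5U	75.5	1.9
Ce21U	77.7	1.4
A4G	77.9	1.7
G45A	79.4	2.3
A38G	80.4	2.2
A29G	81.6	3.3
U19C	85.3	3.4
A59G	85.4	2.7
G26A	88.9	3.2
U33G	98.0	2.8
U51C	101	3.8
G17A	102	2.5
C12U	105	2.8
Ge23A	105	4.2
G15A	107	2.9
C48U	109	6.5
U60C	113	1.7
C40U	116	3.8
U39G	129	2.4
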