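Mutant	Position in FMN Riboswitch	Base Wild-Type (WT)	Base mutant	Riboflavin concentration (ng mL-1)
ROS20	6	C	T	18
ROS21	41	C	T	2.5
ROS22	31	G	A	6.5
ROS23	102	G	A	16
ROS25	105	G	A	35
ROS26	81	G	A	4.5
ROS29	64	G	A	8
WT	-	-	-	< 0.2
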