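base	-5	-4	-3	-2	-1	+1	+2	+3	+4	+5	+6	+7	+8
A	0.2082	0.1306	0.3720	1.4204	-1.5830	-8.3696	-8.9985	1.0932	1.4771	-1.9859	-0.7113	0.0161	-0.5293
C	0.5104	0.6957	1.0657	-0.9485	-2.3528	-10.4401	-5.2125	-2.4697	-1.0419	-1.4937	0.0111	0.3350	0.6644
G	-0.7793	-0.4697	-0.9095	-1.4947	1.2021	1.4713	-9.4051	0.3050	-1.2529	1.1711	-0.6257	-0.0225	-0.3267
T	0.2021	-0.3378	-1.1008	-0.5682	-1.9475	-10.5499	2.2380	-3.5486	-1.0776	-1.8007	1.0212	-0.3701	0.2039
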