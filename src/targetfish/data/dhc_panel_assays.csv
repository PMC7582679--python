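compound_id,target_id,mean,sd
1,CYP19A1,13.8,2.0
2,CYP19A1,21.1,11.7
3,CYP19A1,-1.0,12.0
4,CYP19A1,3.5,19.0
5,CYP19A1,17.0,2.0
6,CYP19A1,13.8,4.4
7,CYP19A1,9.4,3.5
8,CYP19A1,5.9,3.5
9,CYP19A1,0.67,4.0
10,CYP19A1,0,5.8
1,HSD17B2,-50.7,22.7
2,HSD17B2,-14.1,27.1
3,HSD17B2,-26.3,28.8
4,HSD17B2,-31.2,8.1
5,HSD17B2,-17.6,39.0
6,HSD17B2,-39,29.9
7,HSD17B2,-40.5,22.9
8,HSD17B2,-49.8,21.4
9,HSD17B2,-37.1,44.3
10,HSD17B2,-32.2,15.4
1,HSD17B3,1.7,4.5
2,HSD17B3,43.8,4.7
3,HSD17B3,-28.0,20.5
4,HSD17B3,52.7,49.6
5,HSD17B3,32.1,27.2
6,HSD17B3,16.7,14.5
7,HSD17B3,20.2,17.7
8,HSD17B3,-0.6,10.0
9,HSD17B3,45.8,14.2
10,HSD17B3,37.5,23.9
1,AKR1C3,24.8,5.9
2,AKR1C3,15.5,4.9
3,AKR1C3,13.8,10.0
4,AKR1C3,34.4,5.1
5,AKR1C3,35.2,3.8
6,AKR1C3,-6.1,6.8
7,AKR1C3,-7.2,8.9
8,AKR1C3,5.3,11.5
9,AKR1C3,-1.3,1.9
10,AKR1C3,7.4,11.8
1,ALOX5,85.4,9.3
2,ALOX5,99.2,1.2
3,ALOX5,54.1,11.6
4,ALOX5,39.2,11.1
5,ALOX5,47.2,24.2
6,ALOX5,34.8,14.2
7,ALOX5,40.8,4.1
8,ALOX5,45.5,2.7
9,ALOX5,31.8,29.4
10,ALOX5,7.7,6.0
1,PTGS1,43.5,7.2
2,PTGS1,48.1,12.0
3,PTGS1,53.9,5.3
4,PTGS1,24.4,4.2
5,PTGS1,49.5,1.9
6,PTGS1,12.34,29.0
7,PTGS1,-4.2,45.6
8,PTGS1,15.3,26.4
9,PTGS1,-11.4,15.1
10,PTGS1,11.1,13.2
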