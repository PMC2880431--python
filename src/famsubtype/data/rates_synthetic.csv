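age_lo,age_hi,period_lo,period_hi,rate
0.0,5.0,1960.0,1965.0,0.0
0.0,5.0,1965.0,1970.0,0.0
0.0,5.0,1970.0,1975.0,0.0
0.0,5.0,1975.0,1980.0,0.0
0.0,5.0,1980.0,1985.0,0.0
0.0,5.0,1985.0,1990.0,0.0
0.0,5.0,1990.0,1995.0,0.0
0.0,5.0,1995.0,2000.0,0.0
0.0,5.0,2000.0,2005.0,0.0
0.0,5.0,2005.0,2010.0,0.0
5.0,10.0,1960.0,1965.0,0.0
5.0,10.0,1965.0,1970.0,0.0
5.0,10.0,1970.0,1975.0,0.0
5.0,10.0,1975.0,1980.0,0.0
5.0,10.0,1980.0,1985.0,0.0
5.0,10.0,1985.0,1990.0,0.0
5.0,10.0,1990.0,1995.0,0.0
5.0,10.0,1995.0,2000.0,0.0
5.0,10.0,2000.0,2005.0,0.0
5.0,10.0,2005.0,2010.0,0.0
10.0,15.0,1960.0,1965.0,0.0
10.0,15.0,1965.0,1970.0,0.0
10.0,15.0,1970.0,1975.0,0.0
10.0,15.0,1975.0,1980.0,0.0
10.0,15.0,1980.0,1985.0,0.0
10.0,15.0,1985.0,1990.0,0.0
10.0,15.0,1990.0,1995.0,0.0
10.0,15.0,1995.0,2000.0,0.0
10.0,15.0,2000.0,2005.0,0.0
10.0,15.0,2005.0,2010.0,0.0
15.0,20.0,1960.0,1965.0,0.0
15.0,20.0,1965.0,1970.0,0.0
15.0,20.0,1970.0,1975.0,0.0
15.0,20.0,1975.0,1980.0,0.0
15.0,20.0,1980.0,1985.0,0.0
15.0,20.0,1985.0,1990.0,0.0
15.0,20.0,1990.0,1995.0,0.0
15.0,20.0,1995.0,2000.0,0.0
15.0,20.0,2000.0,2005.0,0.0
15.0,20.0,2005.0,2010.0,0.0
20.0,25.0,1960.0,1965.0,4.228728316681628e-05
20.0,25.0,1965.0,1970.0,4.2710155998484444e-05
20.0,25.0,1970.0,1975.0,4.313725755846929e-05
20.0,25.0,1975.0,1980.0,4.356863013405397e-05
20.0,25.0,1980.0,1985.0,4.400431643539452e-05
20.0,25.0,1985.0,1990.0,4.4444359599748474e-05
20.0,25.0,1990.0,1995.0,4.488880319574596e-05
20.0,25.0,1995.0,2000.0,4.533769122770341e-05
20.0,25.0,2000.0,2005.0,4.579106813998045e-05
20.0,25.0,2005.0,2010.0,4.6248978821380246e-05
25.0,30.0,1960.0,1965.0,7.785957633694615e-05
25.0,30.0,1965.0,1970.0,7.863817210031561e-05
25.0,30.0,1970.0,1975.0,7.942455382131877e-05
25.0,30.0,1975.0,1980.0,8.021879935953195e-05
25.0,30.0,1980.0,1985.0,8.102098735312727e-05
25.0,30.0,1985.0,1990.0,8.183119722665856e-05
25.0,30.0,1990.0,1995.0,8.264950919892515e-05
25.0,30.0,1995.0,2000.0,8.347600429091438e-05
25.0,30.0,2000.0,2005.0,8.431076433382354e-05
25.0,30.0,2005.0,2010.0,8.515387197716176e-05
30.0,35.0,1960.0,1965.0,0.0001416310632699346
30.0,35.0,1965.0,1970.0,0.00014304737390263394
30.0,35.0,1970.0,1975.0,0.0001444778476416603
30.0,35.0,1975.0,1980.0,0.00014592262611807686
30.0,35.0,1980.0,1985.0,0.00014738185237925765
30.0,35.0,1985.0,1990.0,0.00014885567090305025
30.0,35.0,1990.0,1995.0,0.00015034422761208075
30.0,35.0,1995.0,2000.0,0.00015184766988820154
30.0,35.0,2000.0,2005.0,0.00015336614658708356
30.0,35.0,2005.0,2010.0,0.0001548998080529544
35.0,40.0,1960.0,1965.0,0.00025219655682514133
35.0,40.0,1965.0,1970.0,0.0002547185223933927
35.0,40.0,1970.0,1975.0,0.00025726570761732667
35.0,40.0,1975.0,1980.0,0.00025983836469349993
35.0,40.0,1980.0,1985.0,0.00026243674834043493
35.0,40.0,1985.0,1990.0,0.0002650611158238393
35.0,40.0,1990.0,1995.0,0.00026771172698207774
35.0,40.0,1995.0,2000.0,0.00027038884425189847
35.0,40.0,2000.0,2005.0,0.00027309273269441746
35.0,40.0,2005.0,2010.0,0.0002758236600213616
40.0,45.0,1960.0,1965.0,0.00043322051482331647
40.0,45.0,1965.0,1970.0,0.0004375527199715496
40.0,45.0,1970.0,1975.0,0.00044192824717126513
40.0,45.0,1975.0,1980.0,0.00044634752964297774
40.0,45.0,1980.0,1985.0,0.00045081100493940757
40.0,45.0,1985.0,1990.0,0.0004553191149888017
40.0,45.0,1990.0,1995.0,0.0004598723061386897
40.0,45.0,1995.0,2000.0,0.0004644710292000766
40.0,45.0,2000.0,2005.0,0.00046911573949207737
40.0,45.0,2005.0,2010.0,0.00047380689688699806
45.0,50.0,1960.0,1965.0,0.0007035140185728596
45.0,50.0,1965.0,1970.0,0.0007105491587585883
45.0,50.0,1970.0,1975.0,0.0007176546503461741
45.0,50.0,1975.0,1980.0,0.0007248311968496358
45.0,50.0,1980.0,1985.0,0.0007320795088181322
45.0,50.0,1985.0,1990.0,0.0007394003039063136
45.0,50.0,1990.0,1995.0,0.0007467943069453767
45.0,50.0,1995.0,2000.0,0.0007542622500148305
45.0,50.0,2000.0,2005.0,0.0007618048725149788
45.0,50.0,2005.0,2010.0,0.0007694229212401285
50.0,55.0,1960.0,1965.0,0.0010562615870354708
50.0,55.0,1965.0,1970.0,0.0010668242029058255
50.0,55.0,1970.0,1975.0,0.0010774924449348836
50.0,55.0,1975.0,1980.0,0.0010882673693842324
50.0,55.0,1980.0,1985.0,0.0010991500430780749
50.0,55.0,1985.0,1990.0,0.0011101415435088558
50.0,55.0,1990.0,1995.0,0.0011212429589439444
50.0,55.0,1995.0,2000.0,0.0011324553885333837
50.0,55.0,2000.0,2005.0,0.0011437799424187176
50.0,55.0,2005.0,2010.0,0.0011552177418429046
55.0,60.0,1960.0,1965.0,0.0014437384129645295
55.0,60.0,1965.0,1970.0,0.0014581757970941749
55.0,60.0,1970.0,1975.0,0.0014727575550651166
55.0,60.0,1975.0,1980.0,0.0014874851306157675
55.0,60.0,1980.0,1985.0,0.0015023599819219255
55.0,60.0,1985.0,1990.0,0.0015173835817411448
55.0,60.0,1990.0,1995.0,0.0015325574175585562
55.0,60.0,1995.0,2000.0,0.0015478829917341416
55.0,60.0,2000.0,2005.0,0.0015633618216514833
55.0,60.0,2005.0,2010.0,0.0015789954398679978
60.0,65.0,1960.0,1965.0,0.0017964859814271403
60.0,65.0,1965.0,1970.0,0.0018144508412414118
60.0,65.0,1970.0,1975.0,0.0018325953496538259
60.0,65.0,1975.0,1980.0,0.001850921303150364
60.0,65.0,1980.0,1985.0,0.0018694305161818677
60.0,65.0,1985.0,1990.0,0.0018881248213436866
60.0,65.0,1990.0,1995.0,0.0019070060695571235
60.0,65.0,1995.0,2000.0,0.0019260761302526946
60.0,65.0,2000.0,2005.0,0.0019453368915552218
60.0,65.0,2005.0,2010.0,0.0019647902604707735
65.0,70.0,1960.0,1965.0,0.0020667794851766835
65.0,70.0,1965.0,1970.0,0.00208744728002845
65.0,70.0,1970.0,1975.0,0.002108321752828735
65.0,70.0,1975.0,1980.0,0.002129404970357022
65.0,70.0,1980.0,1985.0,0.0021506990200605924
65.0,70.0,1985.0,1990.0,0.0021722060102611985
65.0,70.0,1990.0,1995.0,0.0021939280703638106
65.0,70.0,1995.0,2000.0,0.0022158673510674484
65.0,70.0,2000.0,2005.0,0.002238026024578123
65.0,70.0,2005.0,2010.0,0.002260406284823904
70.0,75.0,1960.0,1965.0,0.002247803443174859
70.0,75.0,1965.0,1970.0,0.0022702814776066073
70.0,75.0,1970.0,1975.0,0.0022929842923826737
70.0,75.0,1975.0,1980.0,0.0023159141353065
70.0,75.0,1980.0,1985.0,0.002339073276659565
70.0,75.0,1985.0,1990.0,0.002362464009426161
70.0,75.0,1990.0,1995.0,0.002386088649520423
70.0,75.0,1995.0,2000.0,0.0024099495360156266
70.0,75.0,2000.0,2005.0,0.0024340490313757832
70.0,75.0,2005.0,2010.0,0.0024583895216895406
75.0,80.0,1960.0,1965.0,0.0023583689367300655
75.0,80.0,1965.0,1970.0,0.0023819526260973663
75.0,80.0,1970.0,1975.0,0.00240577215235834
75.0,80.0,1975.0,1980.0,0.002429829873881923
75.0,80.0,1980.0,1985.0,0.0024541281726207427
75.0,80.0,1985.0,1990.0,0.00247866945434695
75.0,80.0,1990.0,1995.0,0.0025034561488904198
75.0,80.0,1995.0,2000.0,0.0025284907103793235
75.0,80.0,2000.0,2005.0,0.002553775617483117
75.0,80.0,2005.0,2010.0,0.002579313373657948
80.0,85.0,1960.0,1965.0,0.002422140423663054
80.0,85.0,1965.0,1970.0,0.0024463618278996848
80.0,85.0,1970.0,1975.0,0.0024708254461786815
80.0,85.0,1975.0,1980.0,0.002495533700640468
80.0,85.0,1980.0,1985.0,0.002520489037646873
80.0,85.0,1985.0,1990.0,0.002545693928023342
80.0,85.0,1990.0,1995.0,0.0025711508673035752
80.0,85.0,1995.0,2000.0,0.002596862375976611
80.0,85.0,2000.0,2005.0,0.002622830999736377
80.0,85.0,2005.0,2010.0,0.0026490593097337404
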